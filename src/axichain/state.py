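"""One synchronous snapshot of every dynamical variable in the chain.

Per-cell scalars: activity ``s``, cell type ``p``, self-weight ``js``,
boundary-marker level ``b``. Per-junction scalar: gap-junction weight ``jg``
(junction k joins cells k and k+1; n_cells-1 of them). Per-cell controller
vectors: intrinsic states ``r`` (9 nodes) and boundary-controller states ``y``
(6 nodes), stored node-major as (..., nodes, cells).

All fields accept identical leading batch axes.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .config import ModelConfig
from .params import IC_MIRROR, BC_MIRROR


@dataclass
class ModelState:
    s: np.ndarray    # (..., n)
    p: np.ndarray    # (..., n)
    js: np.ndarray   # (..., n)
    b: np.ndarray    # (..., n)
    jg: np.ndarray   # (..., n-1)
    r: np.ndarray    # (..., 9, n)
    y: np.ndarray    # (..., 6, n)

    @property
    def n_cells(self) -> int:
        return self.s.shape[-1]

    @property
    def batch_shape(self) -> tuple:
        return self.s.shape[:-1]

    def field_names(self) -> list:
        return [f.name for f in fields(self)]

    def copy(self) -> "ModelState":
        return ModelState(**{f.name: np.array(getattr(self, f.name))
                             for f in fields(self)})

    def map(self, fn) -> "ModelState":
        return ModelState(**{f.name: fn(f.name, getattr(self, f.name))
                             for f in fields(self)})

    def select(self, index) -> "ModelState":
        return self.map(lambda _, a: np.array(a[index]))

    def all_finite(self) -> bool:
        return all(np.all(np.isfinite(getattr(self, f.name)))
                   for f in fields(self))

    def max_abs(self) -> float:
        return max(float(np.max(np.abs(getattr(self, f.name))))
                   if getattr(self, f.name).size else 0.0
                   for f in fields(self))

    def allclose(self, other: "ModelState", **kw) -> bool:
        return all(np.allclose(getattr(self, f.name), getattr(other, f.name), **kw)
                   for f in fields(self))

    def mirror(self) -> "ModelState":
        """Reverse the cell order (and junction order) and flip the
        anterior/posterior columns within each controller."""
        rev = slice(None, None, -1)
        return ModelState(
            s=np.array(self.s[..., rev]),
            p=np.array(self.p[..., rev]),
            js=np.array(self.js[..., rev]),
            b=np.array(self.b[..., rev]),
            jg=np.array(self.jg[..., rev]),
            r=np.array(self.r[..., IC_MIRROR, :][..., rev]),
            y=np.array(self.y[..., BC_MIRROR, :][..., rev]),
        )


def init_state(config: ModelConfig, mode: str = "homogeneous",
               batch_shape: tuple = ()) -> ModelState:
    """The featureless starting tissue: every variable exactly zero."""
    if mode != "homogeneous":
        raise ValueError(f"unknown init mode {mode!r}")
    n = config.n_cells
    return ModelState(
        s=np.zeros(batch_shape + (n,)),
        p=np.zeros(batch_shape + (n,)),
        js=np.zeros(batch_shape + (n,)),
        b=np.zeros(batch_shape + (n,)),
        jg=np.zeros(batch_shape + (n - 1,)),
        r=np.zeros(batch_shape + (config.ic_nodes, n)),
        y=np.zeros(batch_shape + (config.bc_nodes, n)),
    )
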