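"""The trainable "genome": one shared parameter set governing every cell.

Weight blocks (names follow the serialized form):

* ``ug_anterior`` / ``ug_posterior`` — 3 weights each, reading the anterior /
  posterior column of a cell's intrinsic controller and driving the cell's
  anterior / posterior gap junction. The two blocks are distinct parameters,
  which is what gives each cell its planar-cell-polarity character.
* ``us``, ``us_bias`` — central intrinsic column -> self-weight.
* ``up``, ``up_bias`` — all 9 intrinsic nodes -> cell type.
* ``v`` — cell activity -> all 9 intrinsic nodes.
* ``l``, ``l_bias`` — intra-lattice coupling of the intrinsic controller
  (one shared weight per directed 4-neighbor grid edge, stored as a masked
  9x9 matrix) plus per-node constant drive.
* ``m_in``, ``m_lat``, ``m_bias`` — boundary-marker input, intra-lattice
  coupling (masked 6x6) and per-node constant drive of the boundary
  controller.
* ``m_out_anterior`` / ``m_out_posterior`` — 1st / 3rd boundary-controller
  column -> boundary-marker signal sent to the anterior / posterior neighbor.
* ``m_out_self`` — central boundary-controller column -> the cell's own
  boundary marker (the analogue of the intrinsic central column driving the
  cell's own self-weight). Without a self contribution the asymptotic marker
  field obeys pole_1 + pole_n = 2 x interior, making the doubled-pole target
  pattern unrepresentable at equilibrium.
* ``jmax`` — gap-junction saturation bound (scalar > 0).

Weights and biases are initialized i.i.d. uniform on [-1, 1] and ``jmax``
uniform on [1, 2]. The bias terms are what let a homogeneous all-zero tissue
break symmetry and develop a pattern at all: with every bias zero the all-zero
state is a fixed point of the dynamics for any weights.

All fields accept identical leading batch axes, so an ensemble of genomes can
be stepped and trained in lockstep.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
import json

import numpy as np

# Node ordering on an R x C grid is row-major: node j = C*row + col.
IC_SHAPE = (3, 3)
BC_SHAPE = (2, 3)


def _col_indices(rows: int, cols: int, col: int) -> np.ndarray:
    return np.arange(rows) * cols + col


IC_ANTERIOR = _col_indices(3, 3, 0)   # [0, 3, 6]
IC_CENTRAL = _col_indices(3, 3, 1)    # [1, 4, 7]
IC_POSTERIOR = _col_indices(3, 3, 2)  # [2, 5, 8]
BC_ANTERIOR = _col_indices(2, 3, 0)   # [0, 3]
BC_CENTRAL = _col_indices(2, 3, 1)    # [1, 4]
BC_POSTERIOR = _col_indices(2, 3, 2)  # [2, 5]


def grid_edge_mask(rows: int, cols: int) -> np.ndarray:
    """Directed 4-neighbor adjacency mask (no wraparound) of an R x C grid.

    mask[j, k] is True when node k is a grid neighbor of node j, i.e. the
    coupling weight from k into j is trainable.
    """
    n = rows * cols
    mask = np.zeros((n, n), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            j = r * cols + c
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    mask[j, rr * cols + cc] = True
    return mask


IC_EDGE_MASK = grid_edge_mask(*IC_SHAPE)  # 24 directed edges
BC_EDGE_MASK = grid_edge_mask(*BC_SHAPE)  # 14 directed edges


def mirror_permutation(rows: int, cols: int) -> np.ndarray:
    """Node permutation flipping anterior and posterior grid columns."""
    perm = np.empty(rows * cols, dtype=int)
    for r in range(rows):
        for c in range(cols):
            perm[r * cols + c] = r * cols + (cols - 1 - c)
    return perm


IC_MIRROR = mirror_permutation(*IC_SHAPE)
BC_MIRROR = mirror_permutation(*BC_SHAPE)


@dataclass
class Parameters:
    ug_anterior: np.ndarray   # (..., 3)
    ug_posterior: np.ndarray  # (..., 3)
    us: np.ndarray            # (..., 3)
    us_bias: np.ndarray       # (...)
    up: np.ndarray            # (..., 9)
    up_bias: np.ndarray       # (...)
    v: np.ndarray             # (..., 9)
    l: np.ndarray             # (..., 9, 9), masked by IC_EDGE_MASK
    l_bias: np.ndarray        # (..., 9)
    m_in: np.ndarray          # (..., 6)
    m_lat: np.ndarray         # (..., 6, 6), masked by BC_EDGE_MASK
    m_bias: np.ndarray        # (..., 6)
    m_out_anterior: np.ndarray   # (..., 2)
    m_out_self: np.ndarray       # (..., 2)
    m_out_posterior: np.ndarray  # (..., 2)
    jmax: np.ndarray          # (...)

    # trailing (non-batch) shape of every field
    FIELD_SHAPES = {
        "ug_anterior": (3,), "ug_posterior": (3,),
        "us": (3,), "us_bias": (),
        "up": (9,), "up_bias": (),
        "v": (9,),
        "l": (9, 9), "l_bias": (9,),
        "m_in": (6,), "m_lat": (6, 6), "m_bias": (6,),
        "m_out_anterior": (2,), "m_out_self": (2,), "m_out_posterior": (2,),
        "jmax": (),
    }

    @property
    def batch_shape(self) -> tuple:
        return np.shape(self.jmax)

    def field_names(self) -> list:
        return [f.name for f in fields(self)]

    def copy(self) -> "Parameters":
        return Parameters(**{f.name: np.array(getattr(self, f.name))
                             for f in fields(self)})

    def map(self, fn) -> "Parameters":
        return Parameters(**{f.name: fn(f.name, getattr(self, f.name))
                             for f in fields(self)})

    def select(self, index) -> "Parameters":
        """Select one genome (or a sub-batch) out of a batched parameter set."""
        return self.map(lambda _, a: np.array(a[index]))

    def mirror(self) -> "Parameters":
        """Swap anterior and posterior roles of every block (the parameter
        half of the chain-reflection symmetry)."""
        pi, pb = IC_MIRROR, BC_MIRROR
        return Parameters(
            ug_anterior=np.array(self.ug_posterior),
            ug_posterior=np.array(self.ug_anterior),
            us=np.array(self.us),
            us_bias=np.array(self.us_bias),
            up=np.array(self.up[..., pi]),
            up_bias=np.array(self.up_bias),
            v=np.array(self.v[..., pi]),
            l=np.array(self.l[..., pi, :][..., :, pi]),
            l_bias=np.array(self.l_bias[..., pi]),
            m_in=np.array(self.m_in[..., pb]),
            m_lat=np.array(self.m_lat[..., pb, :][..., :, pb]),
            m_bias=np.array(self.m_bias[..., pb]),
            m_out_anterior=np.array(self.m_out_posterior),
            m_out_self=np.array(self.m_out_self),
            m_out_posterior=np.array(self.m_out_anterior),
            jmax=np.array(self.jmax),
        )

    def zero_like(self) -> "Parameters":
        return self.map(lambda _, a: np.zeros_like(a))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {f.name: np.asarray(getattr(self, f.name)).tolist()
                for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "Parameters":
        kwargs = {}
        for name in cls.FIELD_SHAPES:
            if name not in d:
                raise KeyError(f"missing parameter block {name!r}")
            kwargs[name] = np.asarray(d[name], dtype=float)
        return cls(**kwargs)

    def to_json(self, path, *, provenance: dict | None = None) -> None:
        payload = {"blocks": self.to_dict()}
        if provenance:
            payload["provenance"] = provenance
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Parameters":
        with open(path) as fh:
            payload = json.load(fh)
        blocks = payload["blocks"] if "blocks" in payload else payload
        return cls.from_dict(blocks)


def zero_parameters(batch_shape: tuple = ()) -> Parameters:
    return Parameters(**{
        name: np.zeros(batch_shape + shape)
        for name, shape in Parameters.FIELD_SHAPES.items()
    })


def init_parameters(seed: int, config=None, batch_shape: tuple = ()) -> Parameters:
    """Draw a random genome: u, v, l, m blocks (weights and biases) i.i.d.
    uniform on [-1, 1]; jmax uniform on [1, 2]. Same seed, same genome."""
    rng = np.random.default_rng(seed)
    kwargs = {}
    for name, shape in Parameters.FIELD_SHAPES.items():
        full = batch_shape + shape
        if name == "jmax":
            kwargs[name] = rng.uniform(1.0, 2.0, size=full)
        else:
            kwargs[name] = rng.uniform(-1.0, 1.0, size=full)
    kwargs["l"] = kwargs["l"] * IC_EDGE_MASK
    kwargs["m_lat"] = kwargs["m_lat"] * BC_EDGE_MASK
    if batch_shape == ():
        kwargs = {k: (np.asarray(a)[()] if np.ndim(a) == 0 else np.asarray(a))
                  for k, a in kwargs.items()}
        kwargs["jmax"] = np.float64(kwargs["jmax"])
        kwargs["us_bias"] = np.float64(kwargs["us_bias"])
        kwargs["up_bias"] = np.float64(kwargs["up_bias"])
    return Parameters(**kwargs)


def stack_parameters(param_list) -> Parameters:
    """Stack a list of genomes along a new leading batch axis."""
    return Parameters(**{
        name: np.stack([np.asarray(getattr(p, name)) for p in param_list])
        for name in Parameters.FIELD_SHAPES
    })
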