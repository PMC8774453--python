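"""Model geometry and integration constants.

The model is a finite linear chain of ``n_cells`` cells. Each cell carries an
intrinsic signaling controller laid out on a 3x3 grid (9 nodes) and a boundary
signaling controller on a 2x3 grid (6 nodes). Time advances in synchronous
explicit-Euler updates of ``dt`` simulation-seconds; 100 updates make one
simulation-second at the default ``dt``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class ModelConfig:
    n_cells: int = 12
    ic_rows: int = 3
    ic_cols: int = 3
    bc_rows: int = 2
    bc_cols: int = 3
    dt: float = 0.01
    default_horizon: int = 4000

    def __post_init__(self) -> None:
        # Patterning needs a chain (>= 2 cells); a 1-cell "chain" is allowed
        # solely for the isolated-cell clamping assay (it has no junctions).
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.default_horizon < 0:
            raise ValueError("default_horizon must be >= 0")

    @property
    def n_junctions(self) -> int:
        return self.n_cells - 1

    @property
    def ic_nodes(self) -> int:
        return self.ic_rows * self.ic_cols

    @property
    def bc_nodes(self) -> int:
        return self.bc_rows * self.bc_cols

    def with_cells(self, n_cells: int) -> "ModelConfig":
        """Same controllers and step size on a chain of a different length."""
        return ModelConfig(
            n_cells=n_cells,
            ic_rows=self.ic_rows,
            ic_cols=self.ic_cols,
            bc_rows=self.bc_rows,
            bc_cols=self.bc_cols,
            dt=self.dt,
            default_horizon=self.default_horizon,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def default_config() -> ModelConfig:
    """The reference configuration: 12 cells (11 gap junctions), 3x3 and 2x3
    controller lattices, dt = 0.01 and a 4000-step (40 simulation-second)
    developmental horizon."""
    return ModelConfig()
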