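"""Target patterns, the training loss, and pattern-match scores.

Two idealized targets drive the parameter search: a gradient-like activity
pattern (positive anterior half, negative posterior half, zero at both poles)
and a boundary-marker pattern with value 2 at the two pole ("stop") cells and
1 everywhere in between. The loss is a plain MSE against each target, equally
weighted, averaged over cells and over the final window of the rollout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TargetSpec:
    activity_target: np.ndarray
    boundary_target: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.activity_target.shape[-1]

    @classmethod
    def for_cells(cls, n: int) -> "TargetSpec":
        return cls(activity_target=make_activity_target(n),
                   boundary_target=make_boundary_target(n))


def make_activity_target(n: int) -> np.ndarray:
    """Antisymmetric axial gradient: zero at both poles, linear ramp from +1
    (cell 2) down to -1 (cell n-1) in between."""
    if n < 4:
        raise ValueError("activity target needs n >= 4")
    t = np.zeros(n)
    interior = np.arange(n - 2)
    t[1:-1] = 1.0 - 2.0 * interior / (n - 3)
    return t


def make_boundary_target(n: int) -> np.ndarray:
    """Boundary-marker target: 2 at the stop cells (both poles), 1 elsewhere."""
    if n < 2:
        raise ValueError("boundary target needs n >= 2")
    t = np.ones(n)
    t[0] = 2.0
    t[-1] = 2.0
    return t


def pattern_loss(trajectory, targets: TargetSpec, window: int = 100):
    """Half the MSE of the activity pattern plus half the MSE of the
    boundary-marker pattern, each averaged over cells and over the final
    ``window`` recorded states."""
    if not 1 <= window <= len(trajectory):
        raise ValueError("window longer than trajectory")
    sl = slice(len(trajectory) - window, None)
    err_s = trajectory.s[sl] - targets.activity_target
    err_b = trajectory.b[sl] - targets.boundary_target
    mse_s = np.mean(err_s ** 2, axis=(0, -1))
    mse_b = np.mean(err_b ** 2, axis=(0, -1))
    return 0.5 * mse_s + 0.5 * mse_b


def activity_match_score(observed, target) -> float:
    """Percent match of the observed activity pattern with the target,
    relative to the maximum mismatch of the sign-flipped target:
    100 (1 - MSE(o, t) / MSE(t, -t)), clipped below at zero."""
    observed = np.asarray(observed, dtype=float)
    target = np.asarray(target, dtype=float)
    if observed.shape[-1] != target.shape[-1]:
        raise ValueError("length mismatch")
    denom = np.mean((2.0 * target) ** 2, axis=-1)
    if np.any(denom == 0):
        raise ValueError("zero target has no sign-flip mismatch scale")
    mse = np.mean((observed - target) ** 2, axis=-1)
    return np.maximum(0.0, 100.0 * (1.0 - mse / denom))


def minmax_normalize(v) -> tuple[np.ndarray, bool]:
    """Min-max normalization over the last axis to [0, 1]. A constant vector
    has no shape; it maps to all zeros with the degenerate flag set."""
    v = np.asarray(v, dtype=float)
    lo = v.min(axis=-1, keepdims=True)
    hi = v.max(axis=-1, keepdims=True)
    span = hi - lo
    degenerate = bool(np.any(span == 0))
    safe = np.where(span == 0, 1.0, span)
    out = np.where(span == 0, 0.0, (v - lo) / safe)
    return out, degenerate


def boundary_match_score(observed_b, target_b) -> float:
    """Percent match of the min-max normalized boundary-marker shape with the
    normalized target, relative to the mismatch of the inverted shape:
    100 (1 - MSE(b_hat, t_hat) / MSE(t_hat, 1 - t_hat)), clipped at zero."""
    observed_b = np.asarray(observed_b, dtype=float)
    target_b = np.asarray(target_b, dtype=float)
    if observed_b.shape[-1] != target_b.shape[-1]:
        raise ValueError("length mismatch")
    t_hat, t_degen = minmax_normalize(target_b)
    if t_degen:
        raise ValueError("constant boundary target cannot be normalized")
    b_hat, _ = minmax_normalize(observed_b)
    denom = np.mean((t_hat - (1.0 - t_hat)) ** 2, axis=-1)
    mse = np.mean((b_hat - t_hat) ** 2, axis=-1)
    return np.maximum(0.0, 100.0 * (1.0 - mse / denom))
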