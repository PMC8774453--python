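"""Perturbation and characterization experiments on a parameterized chain.

These assays probe what a genome can do beyond the task it was selected for:
develop the pattern from featureless conditions, regenerate it from a small
surviving fragment, rescale it to a longer chain, canalize random initial
conditions, and (for a single isolated cell) reveal how much of the patterning
logic lives inside one cell. They run on ANY parameter set; the emergent-
capacity claims (high match scores) hold only for trained genomes and are
asserted as ensemble medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig
from .params import Parameters
from .state import ModelState, init_state
from .dynamics import (step, simulate, simulate_tail, gj_drive,
                       Trajectory, DivergenceError)
from .objectives import (TargetSpec, activity_match_score,
                         boundary_match_score, minmax_normalize)

WINDOW = 100  # final-pattern averaging window (matches the loss window)


@dataclass
class ExperimentResult:
    label: str
    trajectory: object  # Trajectory or TailTrajectory (None for replicates)
    scores: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    final_activity: np.ndarray | None = None
    final_boundary: np.ndarray | None = None


def _final_patterns(traj, window: int = WINDOW):
    w = min(window, len(traj))
    return traj.window_mean("s", w), traj.window_mean("b", w)


def develop_homogeneous(params: Parameters, config: ModelConfig,
                        horizon: int | None = None) -> ExperimentResult:
    """Develop from the all-zero tissue and score the final activity and
    boundary patterns against the targets."""
    if horizon is None:
        horizon = config.default_horizon
    targets = TargetSpec.for_cells(config.n_cells)
    traj = simulate(init_state(config), params, config, horizon)
    s_fin, b_fin = _final_patterns(traj)
    scores = {
        "activity_match": float(activity_match_score(
            s_fin, targets.activity_target)),
        "boundary_match": float(boundary_match_score(
            b_fin, targets.boundary_target)),
    }
    return ExperimentResult(
        label="develop_homogeneous", trajectory=traj, scores=scores,
        provenance={"horizon": horizon, "n_cells": config.n_cells},
        final_activity=s_fin, final_boundary=b_fin)


def cut_to_fragment(state: ModelState, keep_cells: tuple[int, ...]
                    ) -> ModelState:
    """Zero every variable except those owned by the retained cells
    (their s, p, js, b, r, y); all junctions are zeroed. ``keep_cells``
    is 0-based."""
    out = state.map(lambda _, a: np.zeros_like(a))
    keep = list(keep_cells)
    for f in ("s", "p", "js", "b"):
        getattr(out, f)[..., keep] = getattr(state, f)[..., keep]
    out.r[..., :, keep] = state.r[..., :, keep]
    out.y[..., :, keep] = state.y[..., :, keep]
    return out


def middle_two_cells(n: int) -> tuple[int, int]:
    """0-based indices of the retained middle fragment: cells n/2 and n/2+1
    (1-based) for even n; the middle cell and its posterior neighbor
    otherwise."""
    a = (n - 1) // 2 if n % 2 else n // 2 - 1
    return (a, a + 1)


def regenerate_from_fragment(params: Parameters, config: ModelConfig,
                             horizon: int | None = None) -> ExperimentResult:
    """Develop fully, zero everything except the middle two cells, run the
    same horizon again, and compare the regenerated activity pattern with the
    pre-cut one."""
    if horizon is None:
        horizon = config.default_horizon
    targets = TargetSpec.for_cells(config.n_cells)
    traj1 = simulate(init_state(config), params, config, horizon)
    s_pre, b_pre = _final_patterns(traj1)
    frag = cut_to_fragment(traj1.final_state, middle_two_cells(config.n_cells))
    traj2 = simulate(frag, params, config, horizon)
    s_post, b_post = _final_patterns(traj2)
    scores = {
        "regeneration_match": float(activity_match_score(s_post, s_pre))
        if np.any(s_pre != 0) else 100.0,
        "activity_match": float(activity_match_score(
            s_post, targets.activity_target)),
        "boundary_match": float(boundary_match_score(
            b_post, targets.boundary_target)),
    }
    res = ExperimentResult(
        label="regenerate_from_fragment", trajectory=traj2, scores=scores,
        provenance={"horizon": horizon, "n_cells": config.n_cells,
                    "kept_cells_0based": list(middle_two_cells(config.n_cells))},
        final_activity=s_post, final_boundary=b_post)
    res.scores["precut_activity"] = [float(x) for x in s_pre]
    return res


def rescale_develop(params: Parameters, config: ModelConfig, new_n: int,
                    horizon: int | None = None) -> ExperimentResult:
    """Apply the same shared genome to a chain of ``new_n`` cells from the
    all-zero state; targets are regenerated at the new size. At the training
    size this reproduces develop_homogeneous exactly."""
    if new_n < 4:
        raise ValueError("rescale needs new_n >= 4")
    cfg = config.with_cells(new_n)
    if horizon is None:
        horizon = cfg.default_horizon
    res = develop_homogeneous(params, cfg, horizon=horizon)
    res.label = "rescale_develop"
    res.provenance["trained_n_cells"] = config.n_cells
    return res


def sample_random_ic(rng: np.random.Generator, config: ModelConfig,
                     batch_shape: tuple = ()) -> ModelState:
    """One random initial tissue: a uniformly drawn number of 'active' cells
    (positions uniform without replacement) with s ~ U[-1,1] and b ~ U[1,2];
    inactive cells have s = 0 and b = 2; all controller states, cell types,
    junction and self-weights start at 0."""
    n = config.n_cells
    state = init_state(config, batch_shape=batch_shape)
    it = np.ndindex(batch_shape) if batch_shape else [()]
    for idx in it:
        n_active = int(rng.integers(0, n + 1))
        active = rng.choice(n, size=n_active, replace=False)
        s = np.zeros(n)
        b = np.full(n, 2.0)
        s[active] = rng.uniform(-1.0, 1.0, size=n_active)
        b[active] = rng.uniform(1.0, 2.0, size=n_active)
        state.s[idx] = s
        state.b[idx] = b
    return state


def random_ic_ensemble(params: Parameters, config: ModelConfig,
                       count: int = 1000, seed: int = 0,
                       horizon: int | None = None) -> list[ExperimentResult]:
    """Canalization assay: develop ``count`` random initial tissues and score
    each final pattern against the targets. Replicates carry their final
    window patterns (full trajectories are not retained at this scale)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    if horizon is None:
        horizon = config.default_horizon
    rng = np.random.default_rng(seed)
    targets = TargetSpec.for_cells(config.n_cells)
    state0 = sample_random_ic(rng, config, batch_shape=(count,))
    results: list[ExperimentResult] = []
    try:
        tail = simulate_tail(state0, params, config, horizon, window=WINDOW)
        s_fin = tail.window_mean("s", min(WINDOW, len(tail)))
        b_fin = tail.window_mean("b", min(WINDOW, len(tail)))
        diverged = np.zeros(count, dtype=bool)
    except DivergenceError:
        # per-replicate fallback so one bad replicate cannot sink the ensemble
        s_fin = np.zeros((count, config.n_cells))
        b_fin = np.zeros((count, config.n_cells))
        diverged = np.zeros(count, dtype=bool)
        for i in range(count):
            try:
                t = simulate_tail(state0.select(i), params, config, horizon,
                                  window=WINDOW)
                s_fin[i] = t.window_mean("s", min(WINDOW, len(t)))
                b_fin[i] = t.window_mean("b", min(WINDOW, len(t)))
            except DivergenceError:
                diverged[i] = True
    for i in range(count):
        scores = {"diverged": bool(diverged[i])}
        if not diverged[i]:
            scores["activity_match"] = float(activity_match_score(
                s_fin[i], targets.activity_target))
            scores["boundary_match"] = float(boundary_match_score(
                b_fin[i], targets.boundary_target))
        results.append(ExperimentResult(
            label=f"random_ic_{i}", trajectory=None, scores=scores,
            provenance={"seed": seed, "replicate": i, "horizon": horizon},
            final_activity=None if diverged[i] else s_fin[i],
            final_boundary=None if diverged[i] else b_fin[i]))
    return results


def clamp_isolated_cell(params: Parameters, clamp_value: float,
                        horizon: int = 2000, dt: float = 0.01) -> dict:
    """Isolate one cell (no junctions), clamp its activity state at
    ``clamp_value`` (its own s-update suppressed; everything else evolves),
    and report the asymptotic controller states, cell properties, and the two
    junction drives the cell would emit toward hypothetical silent neighbors."""
    cfg = ModelConfig(n_cells=1, dt=dt)
    state = init_state(cfg)
    state.s[...] = clamp_value
    for _ in range(horizon):
        state = step(state, params, cfg)
        state.s[...] = clamp_value  # clamp: suppress the s-update only
    r = state.r[..., 0]
    emitted_anterior = gj_drive(np.zeros(9), r, params)   # as posterior partner
    emitted_posterior = gj_drive(r, np.zeros(9), params)  # as anterior partner
    return {
        "clamp_value": float(clamp_value),
        "r": np.array(r),
        "y": np.array(state.y[..., 0]),
        "p": float(state.p[..., 0]),
        "js": float(state.js[..., 0]),
        "b": float(state.b[..., 0]),
        "emitted_drive_anterior": float(emitted_anterior),
        "emitted_drive_posterior": float(emitted_posterior),
    }


def clamp_sweep(params: Parameters, values=None, horizon: int = 2000) -> dict:
    """Run the isolated-cell assay over a sweep of clamp values; returns
    stacked arrays keyed like the single-assay record."""
    if values is None:
        values = np.arange(-1.0, 1.0 + 1e-9, 0.2)
    records = [clamp_isolated_cell(params, float(v), horizon=horizon)
               for v in values]
    return {
        "clamp_values": np.array([rec["clamp_value"] for rec in records]),
        "r": np.stack([rec["r"] for rec in records]),          # (k, 9)
        "p": np.array([rec["p"] for rec in records]),
        "js": np.array([rec["js"] for rec in records]),
        "b": np.array([rec["b"] for rec in records]),
        "emitted_drive_anterior": np.array(
            [rec["emitted_drive_anterior"] for rec in records]),
        "emitted_drive_posterior": np.array(
            [rec["emitted_drive_posterior"] for rec in records]),
    }


def settling_time(trajectory, rms_tol: float = 1e-4,
                  block: int = 100) -> int | None:
    """Diagnostic: first step at which the block-mean activity pattern
    changes by less than ``rms_tol`` RMS per ``block`` steps. None if the
    trajectory never settles within its recorded span."""
    s = trajectory.s
    n_blocks = s.shape[0] // block
    prev = None
    for bi in range(n_blocks):
        mean = s[bi * block:(bi + 1) * block].mean(axis=0)
        if prev is not None:
            if float(np.sqrt(np.mean((mean - prev) ** 2))) < rms_tol:
                return bi * block
        prev = mean
    return None


def controller_pattern_summary(trajectory: Trajectory) -> dict:
    """Across-network activity profile of each intrinsic controller node at
    the final step: raw vectors (node i over cells) and their min-max
    normalized versions (degenerate constant profiles flagged)."""
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    r_fin = trajectory.r[-1]  # (..., 9, n)
    raw = np.array(r_fin)
    normalized = np.empty_like(raw)
    degenerate = np.zeros(raw.shape[:-1], dtype=bool)
    for j in np.ndindex(raw.shape[:-1]):
        normalized[j], degenerate[j] = minmax_normalize(raw[j])
    return {"raw": raw, "normalized": normalized, "degenerate": degenerate}
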