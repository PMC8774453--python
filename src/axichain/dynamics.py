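"""The synchronous update map of the chain, with exact derivatives.

Every update reads the previous snapshot only (synchronous explicit Euler).
Writing d(b) = 1/(1 + max(b, 0)) for the boundary-marker damping and
a = dt, the one-step map is

    r  <- r  + a d(b) (tanh(L r + v s + c_r) - r)          intrinsic controller
    y  <- y  + a d(b) (tanh(M y + m_in b + c_y) - y)       boundary controller
    p  <- p  + a d(b) (tanh(up . r + c_p) - p)             cell type
    js <- js + a d(b) (tanh(us . r_mid + c_js) - js)       self-weight
    jg <- jg + a dbar (jmax tanh(g) - jg)                  gap junctions
    s  <- s  + a d(b) (tanh(jg_a s_a + jg_p s_p + js s + p) - s)   activity
    b  <- b  + a (g_b - b)                                 boundary marker

where g is the mean of the two flanking cells' junction drives (posterior
intrinsic column of the anterior cell through ug_posterior, anterior column of
the posterior cell through ug_anterior), dbar the mean damping of the two
flanking cells, and g_b the mean of the boundary signals a cell hears: the
facing columns of the existing neighbors' boundary controllers plus the
cell's own central column (interior cells average 3 contributions, pole
cells 2). Every rate except that of b itself is damped
by the cell's boundary-marker level. The c_* are the trainable constant
drives; with them zeroed, the all-zero state is a fixed point.

States are bounded: the leaky-tanh form keeps |x| <= max(|x(0)|, 1) for the
tanh-driven variables and |jg| <= max(|jg(0)|, jmax).

Besides the step itself this module provides its exact linearization:
``jvp_step`` pushes tangent vectors forward (used to integrate causal
Jacobians over long horizons) and ``vjp_step`` pulls cotangents back while
accumulating parameter gradients (the backbone of backpropagation through
time). Both share the nonlinearity evaluations with the step through
``StepCache`` and are validated against central finite differences in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig
from .params import (
    Parameters, zero_parameters,
    IC_ANTERIOR, IC_CENTRAL, IC_POSTERIOR,
    BC_ANTERIOR, BC_CENTRAL, BC_POSTERIOR,
    IC_EDGE_MASK, BC_EDGE_MASK,
)
from .state import ModelState

DIVERGENCE_THRESHOLD = 1e6


class DivergenceError(RuntimeError):
    """A rollout produced a non-finite or runaway state."""

    def __init__(self, step_index: int, message: str | None = None):
        self.step_index = step_index
        super().__init__(message or f"divergent state at step {step_index}")


def damping_factor(b_value):
    """Boundary-marker damping d(b) = 1/(1 + max(b, 0)).

    Monotone decreasing for b >= 0 with d(0) = 1; negative marker levels do
    not amplify (clamped at 1). Acts like an inverse time constant: the more
    boundary-like a cell, the slower all its damped dynamics run.
    """
    return 1.0 / (1.0 + np.maximum(b_value, 0.0))


def _damping_and_derivative(b):
    d = 1.0 / (1.0 + np.maximum(b, 0.0))
    dd = np.where(b > 0.0, -d * d, 0.0)
    return d, dd


def gj_drive(r_anterior_cell, r_posterior_cell, params: Parameters):
    """Joint junction drive of two flanking cells: the mean of the anterior
    cell's posterior-column contribution and the posterior cell's
    anterior-column contribution (the averaging operator g)."""
    r_a = np.asarray(r_anterior_cell)
    r_p = np.asarray(r_posterior_cell)
    if r_a.shape[-1] != 9 or r_p.shape[-1] != 9:
        raise ValueError("controller state vectors must have 9 entries")
    c1 = np.einsum("...c,...c->...", params.ug_posterior, r_a[..., IC_POSTERIOR])
    c2 = np.einsum("...c,...c->...", params.ug_anterior, r_p[..., IC_ANTERIOR])
    return 0.5 * (c1 + c2)


@dataclass
class StepCache:
    """Intermediates of one step, shared by the map and its derivatives."""
    l_eff: np.ndarray
    m_eff: np.ndarray
    d: np.ndarray
    dd: np.ndarray
    dbar: np.ndarray
    th_r: np.ndarray
    th_y: np.ndarray
    th_p: np.ndarray
    th_js: np.ndarray
    g: np.ndarray
    th_g: np.ndarray
    th_s: np.ndarray
    g_b: np.ndarray
    cnt: np.ndarray


def _contributor_counts(n: int) -> np.ndarray:
    # every cell hears its own central column; interior cells also hear both
    # neighbors, pole cells one
    cnt = np.full(n, 3.0)
    cnt[0] -= 1.0
    cnt[-1] -= 1.0
    return cnt


def _received_boundary_signals(y, params):
    """Per-cell summed boundary signal (numerator of the g() mean) for the b
    update: the facing columns of the existing neighbors' boundary
    controllers plus the cell's own central column."""
    e_post = np.einsum("...c,...ci->...i", params.m_out_posterior,
                       y[..., BC_POSTERIOR, :])
    e_ant = np.einsum("...c,...ci->...i", params.m_out_anterior,
                      y[..., BC_ANTERIOR, :])
    e_self = np.einsum("...c,...ci->...i", params.m_out_self,
                       y[..., BC_CENTRAL, :])
    num = np.zeros(np.broadcast_shapes(e_post.shape, e_ant.shape))
    num = num + e_self
    num[..., 1:] += e_post[..., :-1]
    num[..., :-1] += e_ant[..., 1:]
    return num


def make_cache(state: ModelState, params: Parameters,
               config: ModelConfig) -> StepCache:
    n = state.n_cells
    d, dd = _damping_and_derivative(state.b)
    # non-edge entries of the lattice couplings are structurally zero
    l_eff = params.l * IC_EDGE_MASK
    m_eff = params.m_lat * BC_EDGE_MASK

    h_r = (np.matmul(l_eff, state.r)
           + params.v[..., :, None] * state.s[..., None, :]
           + params.l_bias[..., :, None])
    h_y = (np.matmul(m_eff, state.y)
           + params.m_in[..., :, None] * state.b[..., None, :]
           + params.m_bias[..., :, None])
    h_p = (np.einsum("...j,...ji->...i", params.up, state.r)
           + np.asarray(params.up_bias)[..., None])
    h_js = (np.einsum("...c,...ci->...i", params.us, state.r[..., IC_CENTRAL, :])
            + np.asarray(params.us_bias)[..., None])

    c1 = np.einsum("...c,...ck->...k", params.ug_posterior,
                   state.r[..., IC_POSTERIOR, :-1])
    c2 = np.einsum("...c,...ck->...k", params.ug_anterior,
                   state.r[..., IC_ANTERIOR, 1:])
    g = 0.5 * (c1 + c2)

    h_s = np.zeros(np.broadcast_shapes(state.s.shape, state.p.shape))
    h_s = h_s + state.js * state.s + state.p
    h_s[..., 1:] += state.jg * state.s[..., :-1]
    h_s[..., :-1] += state.jg * state.s[..., 1:]

    cnt = _contributor_counts(n)
    g_b = _received_boundary_signals(state.y, params) / cnt

    return StepCache(
        l_eff=l_eff, m_eff=m_eff, d=d, dd=dd, dbar=0.5 * (d[..., :-1] + d[..., 1:]),
        th_r=np.tanh(h_r), th_y=np.tanh(h_y), th_p=np.tanh(h_p),
        th_js=np.tanh(h_js), g=g, th_g=np.tanh(g), th_s=np.tanh(h_s),
        g_b=g_b, cnt=cnt,
    )


def step(state: ModelState, params: Parameters, config: ModelConfig,
         cache: StepCache | None = None) -> ModelState:
    """One synchronous update of every variable from the previous snapshot."""
    c = cache if cache is not None else make_cache(state, params, config)
    a = config.dt
    d = c.d
    jmax = np.asarray(params.jmax)
    return ModelState(
        s=state.s + a * d * (c.th_s - state.s),
        p=state.p + a * d * (c.th_p - state.p),
        js=state.js + a * d * (c.th_js - state.js),
        b=state.b + a * (c.g_b - state.b),
        jg=state.jg + a * c.dbar * (jmax[..., None] * c.th_g - state.jg),
        r=state.r + a * d[..., None, :] * (c.th_r - state.r),
        y=state.y + a * d[..., None, :] * (c.th_y - state.y),
    )


def jvp_step(state: ModelState, params: Parameters, config: ModelConfig,
             tan: ModelState, cache: StepCache | None = None) -> ModelState:
    """Tangent (forward-mode) push-forward of the step at ``state``.

    ``tan`` holds tangent vectors shaped like the state, optionally with
    extra leading axes so a whole block of directions is propagated at once.
    """
    c = cache if cache is not None else make_cache(state, params, config)
    a = config.dt
    d, dd = c.d, c.dd
    jmax = np.asarray(params.jmax)

    t_d = dd * tan.b
    t_dbar = 0.5 * (t_d[..., :-1] + t_d[..., 1:])

    t_h_r = (np.matmul(c.l_eff, tan.r)
             + params.v[..., :, None] * tan.s[..., None, :])
    new_r = tan.r + a * (t_d[..., None, :] * (c.th_r - state.r)
                         + d[..., None, :] * ((1 - c.th_r ** 2) * t_h_r - tan.r))

    t_h_y = (np.matmul(c.m_eff, tan.y)
             + params.m_in[..., :, None] * tan.b[..., None, :])
    new_y = tan.y + a * (t_d[..., None, :] * (c.th_y - state.y)
                         + d[..., None, :] * ((1 - c.th_y ** 2) * t_h_y - tan.y))

    t_h_p = np.einsum("...j,...ji->...i", params.up, tan.r)
    new_p = tan.p + a * (t_d * (c.th_p - state.p)
                         + d * ((1 - c.th_p ** 2) * t_h_p - tan.p))

    t_h_js = np.einsum("...c,...ci->...i", params.us, tan.r[..., IC_CENTRAL, :])
    new_js = tan.js + a * (t_d * (c.th_js - state.js)
                           + d * ((1 - c.th_js ** 2) * t_h_js - tan.js))

    t_g = 0.5 * (np.einsum("...c,...ck->...k", params.ug_posterior,
                           tan.r[..., IC_POSTERIOR, :-1])
                 + np.einsum("...c,...ck->...k", params.ug_anterior,
                             tan.r[..., IC_ANTERIOR, 1:]))
    new_jg = tan.jg + a * (t_dbar * (jmax[..., None] * c.th_g - state.jg)
                           + c.dbar * (jmax[..., None] * (1 - c.th_g ** 2) * t_g
                                       - tan.jg))

    t_h_s = tan.js * state.s + state.js * tan.s + tan.p
    t_h_s = t_h_s + np.zeros(np.broadcast_shapes(t_h_s.shape, tan.s.shape))
    t_h_s[..., 1:] += tan.jg * state.s[..., :-1] + state.jg * tan.s[..., :-1]
    t_h_s[..., :-1] += tan.jg * state.s[..., 1:] + state.jg * tan.s[..., 1:]
    new_s = tan.s + a * (t_d * (c.th_s - state.s)
                         + d * ((1 - c.th_s ** 2) * t_h_s - tan.s))

    t_g_b = _received_boundary_signals(tan.y, params) / c.cnt
    new_b = tan.b + a * (t_g_b - tan.b)

    return ModelState(s=new_s, p=new_p, js=new_js, b=new_b,
                      jg=new_jg, r=new_r, y=new_y)


def vjp_step(state: ModelState, params: Parameters, config: ModelConfig,
             cot: ModelState, cache: StepCache | None = None,
             param_grads: Parameters | None = None
             ) -> tuple[ModelState, Parameters]:
    """Adjoint (reverse-mode) pull-back of the step at ``state``.

    Given cotangents ``cot`` on the *output* of the step, returns the
    cotangents on the input state and accumulates the gradient with respect
    to every parameter block into ``param_grads`` (created when omitted).
    Batch axes of state, params and cotangents must coincide.
    """
    c = cache if cache is not None else make_cache(state, params, config)
    a = config.dt
    d, dd = c.d, c.dd
    jmax = np.asarray(params.jmax)
    if param_grads is None:
        param_grads = zero_parameters(params.batch_shape)

    ad = a * d
    bs = state.batch_shape
    n = state.n_cells

    bar_s = np.zeros(bs + (n,))
    bar_p = np.zeros(bs + (n,))
    bar_js = np.zeros(bs + (n,))
    bar_b = np.zeros(bs + (n,))
    bar_jg = np.zeros(bs + (n - 1,))
    bar_r = np.zeros(bs + (9, n))
    bar_y = np.zeros(bs + (6, n))

    # --- intrinsic controller block -------------------------------------
    w_hr = ad[..., None, :] * (1 - c.th_r ** 2) * cot.r
    bar_r += (1 - ad[..., None, :]) * cot.r
    bar_r += np.matmul(np.swapaxes(c.l_eff, -1, -2), w_hr)
    bar_s += np.einsum("...j,...ji->...i", params.v, w_hr)
    bar_b += a * dd * np.einsum("...ji,...ji->...i", cot.r, c.th_r - state.r)
    param_grads.l += np.einsum("...ji,...ki->...jk", w_hr, state.r) * IC_EDGE_MASK
    param_grads.v += np.einsum("...ji,...i->...j", w_hr, state.s)
    param_grads.l_bias += w_hr.sum(-1)

    # --- boundary controller block --------------------------------------
    w_hy = ad[..., None, :] * (1 - c.th_y ** 2) * cot.y
    bar_y += (1 - ad[..., None, :]) * cot.y
    bar_y += np.matmul(np.swapaxes(c.m_eff, -1, -2), w_hy)
    bar_b += np.einsum("...j,...ji->...i", params.m_in, w_hy)
    bar_b += a * dd * np.einsum("...ji,...ji->...i", cot.y, c.th_y - state.y)
    param_grads.m_lat += np.einsum("...ji,...ki->...jk", w_hy, state.y) * BC_EDGE_MASK
    param_grads.m_in += np.einsum("...ji,...i->...j", w_hy, state.b)
    param_grads.m_bias += w_hy.sum(-1)

    # --- cell type ------------------------------------------------------
    w_hp = ad * (1 - c.th_p ** 2) * cot.p
    bar_p += (1 - ad) * cot.p
    bar_r += params.up[..., :, None] * w_hp[..., None, :]
    bar_b += a * dd * cot.p * (c.th_p - state.p)
    param_grads.up += np.einsum("...i,...ji->...j", w_hp, state.r)
    param_grads.up_bias += w_hp.sum(-1)

    # --- self-weight ----------------------------------------------------
    w_hjs = ad * (1 - c.th_js ** 2) * cot.js
    bar_js += (1 - ad) * cot.js
    bar_r[..., IC_CENTRAL, :] += params.us[..., :, None] * w_hjs[..., None, :]
    bar_b += a * dd * cot.js * (c.th_js - state.js)
    param_grads.us += np.einsum("...i,...ci->...c", w_hjs,
                                state.r[..., IC_CENTRAL, :])
    param_grads.us_bias += w_hjs.sum(-1)

    # --- gap junctions --------------------------------------------------
    w_g = a * c.dbar * jmax[..., None] * (1 - c.th_g ** 2) * cot.jg
    bar_jg += (1 - a * c.dbar) * cot.jg
    bar_r[..., IC_POSTERIOR, :-1] += 0.5 * params.ug_posterior[..., :, None] \
        * w_g[..., None, :]
    bar_r[..., IC_ANTERIOR, 1:] += 0.5 * params.ug_anterior[..., :, None] \
        * w_g[..., None, :]
    param_grads.ug_posterior += 0.5 * np.einsum(
        "...k,...ck->...c", w_g, state.r[..., IC_POSTERIOR, :-1])
    param_grads.ug_anterior += 0.5 * np.einsum(
        "...k,...ck->...c", w_g, state.r[..., IC_ANTERIOR, 1:])
    param_grads.jmax += (a * c.dbar * c.th_g * cot.jg).sum(-1)
    # damping of a junction is the mean of its two flanking cells'
    t_half = 0.5 * a * (jmax[..., None] * c.th_g - state.jg) * cot.jg
    bar_b[..., :-1] += dd[..., :-1] * t_half
    bar_b[..., 1:] += dd[..., 1:] * t_half

    # --- activity -------------------------------------------------------
    w_hs = ad * (1 - c.th_s ** 2) * cot.s
    bar_s += (1 - ad) * cot.s + state.js * w_hs
    bar_s[..., :-1] += state.jg * w_hs[..., 1:]
    bar_s[..., 1:] += state.jg * w_hs[..., :-1]
    bar_jg += state.s[..., :-1] * w_hs[..., 1:] + state.s[..., 1:] * w_hs[..., :-1]
    bar_js += state.s * w_hs
    bar_p += w_hs
    bar_b += a * dd * cot.s * (c.th_s - state.s)

    # --- boundary marker ------------------------------------------------
    bar_b += (1 - a) * cot.b
    w_u = a * cot.b / c.cnt
    e_post_cot = np.zeros(bs + (n,))
    e_ant_cot = np.zeros(bs + (n,))
    e_post_cot[..., :-1] = w_u[..., 1:]
    e_ant_cot[..., 1:] = w_u[..., :-1]
    bar_y[..., BC_POSTERIOR, :] += params.m_out_posterior[..., :, None] \
        * e_post_cot[..., None, :]
    bar_y[..., BC_ANTERIOR, :] += params.m_out_anterior[..., :, None] \
        * e_ant_cot[..., None, :]
    bar_y[..., BC_CENTRAL, :] += params.m_out_self[..., :, None] \
        * w_u[..., None, :]
    param_grads.m_out_posterior += np.einsum(
        "...i,...ci->...c", e_post_cot, state.y[..., BC_POSTERIOR, :])
    param_grads.m_out_anterior += np.einsum(
        "...i,...ci->...c", e_ant_cot, state.y[..., BC_ANTERIOR, :])
    param_grads.m_out_self += np.einsum(
        "...i,...ci->...c", w_u, state.y[..., BC_CENTRAL, :])

    cot_in = ModelState(s=bar_s, p=bar_p, js=bar_js, b=bar_b,
                        jg=bar_jg, r=bar_r, y=bar_y)
    return cot_in, param_grads


# --- trajectories -------------------------------------------------------

@dataclass
class Trajectory:
    """Time-ordered stack of states; arrays are (T+1, ..., field shape)."""
    config: ModelConfig
    s: np.ndarray
    p: np.ndarray
    js: np.ndarray
    b: np.ndarray
    jg: np.ndarray
    r: np.ndarray
    y: np.ndarray
    params_ref: str = ""

    def __len__(self) -> int:
        return self.s.shape[0]

    @property
    def n_steps(self) -> int:
        return len(self) - 1

    def state_at(self, t: int) -> ModelState:
        return ModelState(s=self.s[t], p=self.p[t], js=self.js[t],
                          b=self.b[t], jg=self.jg[t], r=self.r[t],
                          y=self.y[t])

    @property
    def final_state(self) -> ModelState:
        return self.state_at(len(self) - 1)

    def window_mean(self, field: str, window: int) -> np.ndarray:
        """Mean of a field over the final ``window`` recorded states."""
        if not 1 <= window <= len(self):
            raise ValueError("window longer than trajectory")
        return getattr(self, field)[len(self) - window:].mean(axis=0)


def simulate(state: ModelState, params: Parameters, config: ModelConfig,
             n_steps: int) -> Trajectory:
    """Roll the chain forward ``n_steps`` synchronous updates, recording every
    snapshot. Raises :class:`DivergenceError` (with the offending step index)
    if any variable leaves the finite range."""
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    fields = ("s", "p", "js", "b", "jg", "r", "y")
    store = {f: np.empty((n_steps + 1,) + getattr(state, f).shape)
             for f in fields}
    cur = state
    for f in fields:
        store[f][0] = getattr(state, f)
    for t in range(n_steps):
        cur = step(cur, params, config)
        for f in fields:
            store[f][t + 1] = getattr(cur, f)
        if (t + 1) % 200 == 0 or t == n_steps - 1:
            m = np.abs(cur.s).max() if cur.s.size else 0.0
            if not np.isfinite(m) or m > DIVERGENCE_THRESHOLD or not cur.all_finite():
                bad = _first_bad_step(store, fields, t + 1)
                raise DivergenceError(bad)
    return Trajectory(config=config, **store)


def _first_bad_step(store, fields, upto):
    for t in range(upto + 1):
        for f in fields:
            a = store[f][t]
            if not np.all(np.isfinite(a)) or (a.size and
                                              np.abs(a).max() > DIVERGENCE_THRESHOLD):
                return t
    return upto


@dataclass
class TailTrajectory:
    """The final ``window`` snapshots of selected fields of a long rollout
    (duck-typed like :class:`Trajectory` for loss/score evaluation), kept
    memory-light for large ensembles."""
    config: ModelConfig
    s: np.ndarray  # (window, ..., n)
    b: np.ndarray  # (window, ..., n)
    final_state: ModelState
    n_steps: int = 0
    params_ref: str = ""

    def __len__(self) -> int:
        return self.s.shape[0]

    def window_mean(self, field: str, window: int) -> np.ndarray:
        arr = getattr(self, field)
        if not 1 <= window <= arr.shape[0]:
            raise ValueError("window longer than recorded tail")
        return arr[arr.shape[0] - window:].mean(axis=0)


def simulate_tail(state: ModelState, params: Parameters, config: ModelConfig,
                  n_steps: int, window: int = 100) -> TailTrajectory:
    """Roll forward ``n_steps`` updates but record only the last ``window``
    snapshots of the activity and boundary-marker fields (plus the final full
    state). Equivalent to :func:`simulate` followed by slicing, at O(window)
    memory — the workhorse for 100-to-1000-member ensembles."""
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    window = min(window, n_steps + 1)
    s_buf = np.empty((window,) + state.s.shape)
    b_buf = np.empty((window,) + state.b.shape)
    cur = state
    start = n_steps + 1 - window
    if start == 0:
        s_buf[0], b_buf[0] = cur.s, cur.b
    for t in range(n_steps):
        cur = step(cur, params, config)
        if t + 1 >= start:
            s_buf[t + 1 - start] = cur.s
            b_buf[t + 1 - start] = cur.b
        if (t + 1) % 200 == 0 or t == n_steps - 1:
            m = np.abs(cur.s).max() if cur.s.size else 0.0
            if not np.isfinite(m) or m > DIVERGENCE_THRESHOLD or not cur.all_finite():
                raise DivergenceError(t + 1)
    return TailTrajectory(config=config, s=s_buf, b=b_buf, final_state=cur,
                          n_steps=n_steps)


def mirror_transform(state: ModelState, params: Parameters
                     ) -> tuple[ModelState, Parameters]:
    """Reflect the chain: reverse cell (and junction) order, flip the
    anterior/posterior controller columns, and swap the anterior/posterior
    parameter blocks. An involution; the step map commutes with it."""
    return state.mirror(), params.mirror()
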