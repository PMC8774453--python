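"""Causal network integration: multi-timescale Jacobians and signed networks.

The causal influence of a source variable x at time 0 on a target variable y
at time tau is the exact derivative dy(tau)/dx(0) of the tau-step composed
update map, evaluated along the trajectory actually taken (the full model
state provides the context). It is deterministic, signed and directional —
not a statistical estimate. The tensor J[i, j, k] indexes the influenced cell
i, the source node j within the influencing cell k (Eq.-style convention:
cells i,k; node j).

Integration is forward-mode: a block of one-hot tangent vectors (one per
source coordinate) is pushed through the exact linearization of every step.
A finite-difference twin serves as the independent oracle in the tests.

Coarse-graining to a cell-level circuit: for each ordered cell pair the nine
(or six) source-node influences form a small sample; entries flagged as
statistical outliers of that sample become signed directed edges. The default
rule is Tukey's 1.5 IQR fences, with a z-score alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .config import ModelConfig
from .params import Parameters
from .state import ModelState, init_state
from .dynamics import (step, jvp_step, make_cache, simulate,
                       DivergenceError, DIVERGENCE_THRESHOLD)

#: per-cell source/target fields and their node counts
VARIABLE_NODES = {"s": 1, "p": 1, "js": 1, "b": 1, "r": 9, "y": 6}


@dataclass
class CausalTensor:
    values: np.ndarray      # (n, source_nodes, n) = (i, j, k)
    tau: int
    source_var: str
    target_var: str
    base_state_ref: str = "homogeneous"

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def source_nodes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CausalEdge:
    source: int      # influencing cell, 1-based
    target: int      # influenced cell, 1-based
    sign: int        # +1 / -1
    magnitude: float
    source_node: int  # node j within the influencing cell, 1-based


@dataclass
class CausalNetwork:
    n_cells: int
    tau: int
    edges: list = field(default_factory=list)
    extraction_rule: dict = field(default_factory=dict)
    source_var: str = "r"
    target_var: str = "s"

    def edge_keys(self) -> set:
        return {(e.source, e.target, e.sign) for e in self.edges}

    def to_multigraph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph(tau=self.tau, source_var=self.source_var,
                            target_var=self.target_var)
        for i in range(1, self.n_cells + 1):
            g.add_node(i, cell_index=i)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign="+" if e.sign > 0 else "-",
                       magnitude=float(e.magnitude),
                       source_node_j=int(e.source_node))
        return g


@dataclass
class MeanCausalNetwork:
    n_cells: int
    tau: int
    ensemble_size: int
    # (source, target, sign) -> frequency in (0, 1]
    edge_frequency: dict = field(default_factory=dict)

    def to_graph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph(tau=self.tau, ensemble_size=self.ensemble_size)
        for i in range(1, self.n_cells + 1):
            g.add_node(i, cell_index=i)
        for (src, tgt, sign), freq in sorted(self.edge_frequency.items()):
            g.add_edge(src, tgt, sign="+" if sign > 0 else "-",
                       frequency=float(freq))
        return g


def _source_tangent_block(state: ModelState, source_var: str) -> ModelState:
    """One-hot tangent directions for every coordinate of the source variable:
    leading axis K = source_nodes * n, ordered j-major then k."""
    n = state.n_cells
    nodes = VARIABLE_NODES[source_var]
    K = nodes * n
    tan = {f: np.zeros((K,) + getattr(state, f).shape)
           for f in state.field_names()}
    arr = tan[source_var]
    if nodes == 1:
        for k in range(n):
            arr[k, ..., k] = 1.0
    else:
        for j in range(nodes):
            for k in range(n):
                arr[j * n + k, ..., j, k] = 1.0
    return ModelState(**tan)


def causal_jacobian(params: Parameters, init_state_: ModelState | None,
                    tau: int, source_var: str = "r", target_var: str = "s",
                    config: ModelConfig | None = None) -> CausalTensor:
    """Exact Jacobian of the tau-step rollout map: the influence of every
    source coordinate at t=0 on the target variable of every cell at t=tau,
    evaluated along the trajectory from ``init_state_`` (the all-zero
    homogeneous tissue when omitted)."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if source_var not in VARIABLE_NODES or target_var not in VARIABLE_NODES:
        raise ValueError("unknown source or target variable")
    if target_var in ("r", "y"):
        raise ValueError("target must be a per-cell scalar field (s, p, js, b)")
    if config is None:
        config = ModelConfig() if init_state_ is None \
            else ModelConfig(n_cells=init_state_.n_cells)
    if init_state_ is None:
        init_state_ = init_state(config)
        base_ref = "homogeneous"
    else:
        base_ref = "custom"
    n = config.n_cells
    nodes = VARIABLE_NODES[source_var]

    cur = init_state_
    tan = _source_tangent_block(cur, source_var)
    for t in range(tau):
        cache = make_cache(cur, params, config)
        tan = jvp_step(cur, params, config, tan, cache=cache)
        cur = step(cur, params, config, cache=cache)
        if not np.isfinite(cur.s).all() or \
                (cur.s.size and np.abs(cur.s).max() > DIVERGENCE_THRESHOLD):
            raise DivergenceError(t + 1)
    tgt = getattr(tan, target_var)          # (K, n)
    J = tgt.reshape(nodes, n, n)            # (j, k, i)
    J = np.ascontiguousarray(np.moveaxis(J, 2, 0))  # (i, j, k)
    return CausalTensor(values=J, tau=tau, source_var=source_var,
                        target_var=target_var, base_state_ref=base_ref)


def finite_difference_jacobian(params: Parameters,
                               init_state_: ModelState | None, tau: int,
                               source_var: str = "r", target_var: str = "s",
                               h: float = 1e-4,
                               config: ModelConfig | None = None
                               ) -> CausalTensor:
    """Central-difference twin of :func:`causal_jacobian` (the test oracle):
    2 * source-dimension independent rollouts, O(h^2) accurate."""
    if h <= 0:
        raise ValueError("h must be > 0")
    if config is None:
        config = ModelConfig() if init_state_ is None \
            else ModelConfig(n_cells=init_state_.n_cells)
    if init_state_ is None:
        init_state_ = init_state(config)
        base_ref = "homogeneous"
    else:
        base_ref = "custom"
    n = config.n_cells
    nodes = VARIABLE_NODES[source_var]
    J = np.zeros((n, nodes, n))

    def rollout_target(st: ModelState) -> np.ndarray:
        cur = st
        for _ in range(tau):
            cur = step(cur, params, config)
        return np.array(getattr(cur, target_var))

    for j in range(nodes):
        for k in range(n):
            plus = init_state_.copy()
            minus = init_state_.copy()
            if nodes == 1:
                getattr(plus, source_var)[..., k] += h
                getattr(minus, source_var)[..., k] -= h
            else:
                getattr(plus, source_var)[..., j, k] += h
                getattr(minus, source_var)[..., j, k] -= h
            J[:, j, k] = (rollout_target(plus) - rollout_target(minus)) / (2 * h)
    return CausalTensor(values=J, tau=tau, source_var=source_var,
                        target_var=target_var, base_state_ref=base_ref)


def normalize_ci(tensor: CausalTensor) -> tuple[np.ndarray, np.ndarray]:
    """Min-max normalize each (j, k) influence profile over the influenced
    cells i. Returns (normalized (n, nodes, n), degenerate flags (nodes, n))."""
    from .objectives import minmax_normalize
    J = tensor.values
    n, nodes, _ = J.shape
    out = np.empty_like(J)
    degen = np.zeros((nodes, J.shape[2]), dtype=bool)
    for j in range(nodes):
        for k in range(J.shape[2]):
            out[:, j, k], degen[j, k] = minmax_normalize(J[:, j, k])
    return out, degen


# --- outlier rules ------------------------------------------------------

def tukey_outliers(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Boolean mask of entries outside the Tukey fences
    [Q1 - k IQR, Q3 + k IQR] of the sample."""
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values < q1 - k * iqr) | (values > q3 + k * iqr)


def zscore_outliers(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Boolean mask of entries more than k sample standard deviations from
    the sample mean (degenerate zero-spread samples flag nothing)."""
    sd = values.std()
    if sd == 0:
        return np.zeros(values.shape, dtype=bool)
    return np.abs(values - values.mean()) > k * sd


OUTLIER_RULES = {"tukey": tukey_outliers, "zscore": zscore_outliers}


def extract_causal_network(tensor: CausalTensor, rule: str = "tukey",
                           rule_param: float | None = None) -> CausalNetwork:
    """Coarse-grain a causal tensor into a signed directed multigraph over
    cells: for each ordered pair (source cell k, target cell i) the source-
    node influences {J[i, j, k] : j} form the sample; each outlier of that
    sample contributes one edge carrying its sign, magnitude and node index."""
    if not np.all(np.isfinite(tensor.values)):
        raise ValueError("causal tensor has non-finite entries")
    if rule not in OUTLIER_RULES:
        raise ValueError(f"unknown outlier rule {rule!r}")
    fn = OUTLIER_RULES[rule]
    kw = {} if rule_param is None else {"k": rule_param}
    n, nodes, _ = tensor.values.shape
    edges = []
    for k in range(tensor.values.shape[2]):       # influencing cell
        for i in range(n):                        # influenced cell
            sample = tensor.values[i, :, k]
            mask = fn(sample, **kw)
            for j in np.flatnonzero(mask):
                val = sample[j]
                edges.append(CausalEdge(
                    source=k + 1, target=i + 1,
                    sign=1 if val > 0 else -1,
                    magnitude=float(abs(val)), source_node=int(j) + 1))
    return CausalNetwork(
        n_cells=n, tau=tensor.tau, edges=edges,
        extraction_rule={"rule": rule, **({"k": rule_param} if rule_param
                                          is not None else {})},
        source_var=tensor.source_var, target_var=tensor.target_var)


def mean_causal_network(networks: list[CausalNetwork]) -> MeanCausalNetwork:
    """Ensemble mean: the union of (source, target, sign) edge keys weighted
    by the fraction of member networks containing each key."""
    if not networks:
        raise ValueError("empty network list")
    n0, tau0 = networks[0].n_cells, networks[0].tau
    for net in networks[1:]:
        if net.n_cells != n0 or net.tau != tau0:
            raise ValueError("networks must share n_cells and tau")
    counts: dict = {}
    for net in networks:
        for key in net.edge_keys():
            counts[key] = counts.get(key, 0) + 1
    freq = {key: c / len(networks) for key, c in counts.items()}
    return MeanCausalNetwork(n_cells=n0, tau=tau0,
                             ensemble_size=len(networks),
                             edge_frequency=freq)
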