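"""Serialization and export: trajectory/tensor/loss CSVs, parameter and run
JSON records, GraphML and DOT network files, and the YAML run-configuration
format driving the command line.

Coordinate convention everywhere: cells are 1-based, anterior first; junction
k joins cells k and k+1; controller nodes are 1-based row-major within their
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd
import yaml
import networkx as nx

from .config import ModelConfig
from .training import Hyperparameters

PACKAGE_VERSION = "0.1.0"


# --- trajectory / tensor / loss CSV -------------------------------------

def trajectory_to_frame(traj, targets=None, thin: int = 1) -> pd.DataFrame:
    """Long-form table of a trajectory: step, variable, cell_index (1-based),
    node_index (controller node or junction slot; 0 for plain per-cell
    scalars), value. Optionally appends target_s / target_b rows."""
    rows = []
    steps = range(0, len(traj), thin)
    for t in steps:
        for var in ("s", "p", "js", "b"):
            arr = getattr(traj, var)[t]
            for i, v in enumerate(np.atleast_1d(arr)):
                rows.append((t, var, i + 1, 0, float(v)))
        for k, v in enumerate(np.atleast_1d(traj.jg[t])):
            rows.append((t, "jg", k + 1, k + 1, float(v)))
        for var in ("r", "y"):
            arr = getattr(traj, var)[t]
            for j in range(arr.shape[0]):
                for i in range(arr.shape[1]):
                    rows.append((t, var, i + 1, j + 1, float(arr[j, i])))
    if targets is not None:
        for var, arr in (("target_s", targets.activity_target),
                         ("target_b", targets.boundary_target)):
            for i, v in enumerate(arr):
                rows.append((0, var, i + 1, 0, float(v)))
    return pd.DataFrame(rows, columns=["step", "variable", "cell_index",
                                       "node_index", "value"])


def export_trajectory_csv(traj, path, targets=None, thin: int = 1) -> None:
    trajectory_to_frame(traj, targets=targets, thin=thin).to_csv(path,
                                                                 index=False)


def export_tensor_csv(tensor, path) -> None:
    """CSV triples (i, j, k, value) with a JSON header line describing tau
    and the source/target variables."""
    header = json.dumps({"tau": tensor.tau, "source_var": tensor.source_var,
                         "target_var": tensor.target_var,
                         "base_state_ref": tensor.base_state_ref})
    n, nodes, m = tensor.values.shape
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        fh.write("i,j,k,value\n")
        for i in range(n):
            for j in range(nodes):
                for k in range(m):
                    fh.write(f"{i+1},{j+1},{k+1},"
                             f"{float(tensor.values[i, j, k])!r}\n")


def export_loss_csv(run, path) -> None:
    pd.DataFrame({"iteration": run.logged_iterations,
                  "loss": run.loss_history}).to_csv(path, index=False)


def export_run_json(run, path) -> None:
    with open(path, "w") as fh:
        json.dump({"package_version": PACKAGE_VERSION, **run.to_dict()}, fh,
                  indent=1)


# --- network export -----------------------------------------------------

def export_network(network, fmt: str, path) -> None:
    """Write a causal network (or mean causal network) as GraphML or DOT.
    DOT colors positive edges blue and negative edges red."""
    g = network.to_graph() if hasattr(network, "to_graph") \
        else network.to_multigraph()
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "dot":
        _write_dot(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def _write_dot(g: nx.MultiDiGraph, path) -> None:
    # hand-rolled writer: the DOT format is line-per-edge text and the
    # networkx DOT bridge needs pydot, which is not a dependency
    lines = ["digraph causal {"]
    for node, data in sorted(g.nodes(data=True)):
        lines.append(f'  {node} [label="{node}" '
                     f'cell_index={data.get("cell_index", node)}];')
    for u, v, data in g.edges(data=True):
        color = "blue" if data.get("sign") == "+" else "red"
        attrs = [f'color={color}', f'sign="{data.get("sign", "?")}"']
        if "magnitude" in data:
            attrs.append(f'magnitude={data["magnitude"]:.6g}')
        if "source_node_j" in data:
            attrs.append(f'source_node_j={data["source_node_j"]}')
        if "frequency" in data:
            attrs.append(f'frequency={data["frequency"]:.4g}')
            attrs.append(f'penwidth={0.5 + 4 * data["frequency"]:.3g}')
        lines.append(f"  {u} -> {v} [{' '.join(attrs)}];")
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_graphml_network(path) -> nx.MultiDiGraph:
    return nx.read_graphml(path, force_multigraph=True)


# --- run configuration --------------------------------------------------

_MODEL_KEYS = {"n_cells", "ic_rows", "ic_cols", "bc_rows", "bc_cols", "dt",
               "default_horizon"}
_TRAINING_KEYS = {"iterations", "horizon", "learning_rate", "clip_norm",
                  "window", "log_every", "satisfying_threshold"}
_EXPERIMENT_KEYS = {"name", "tau", "count", "new_n", "clamp_values",
                    "horizon", "source_var", "target_var", "rule"}
_TOP_KEYS = {"model", "training", "experiment", "seed", "output_dir"}


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    training: Hyperparameters = field(default_factory=Hyperparameters)
    experiment: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."

    def to_dict(self) -> dict:
        return {"model": self.model.to_dict(),
                "training": self.training.to_dict(),
                "experiment": dict(self.experiment),
                "seed": self.seed, "output_dir": self.output_dir}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


def run_config_from_dict(d: dict) -> RunConfig:
    _check_keys(d, _TOP_KEYS, "run config")
    model_d = d.get("model", {}) or {}
    _check_keys(model_d, _MODEL_KEYS, "model section")
    training_d = d.get("training", {}) or {}
    _check_keys(training_d, _TRAINING_KEYS, "training section")
    exp_d = d.get("experiment", {}) or {}
    _check_keys(exp_d, _EXPERIMENT_KEYS, "experiment section")
    return RunConfig(
        model=ModelConfig(**model_d),
        training=Hyperparameters(**training_d),
        experiment=dict(exp_d),
        seed=int(d.get("seed", 0)),
        output_dir=str(d.get("output_dir", ".")),
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected
    by name, missing ones take the reference defaults (12 cells, 4000-step
    horizon, the documented training hyperparameters)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a mapping")
    return run_config_from_dict(raw)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def provenance_record(seed: int, config: ModelConfig, extra: dict | None = None
                      ) -> dict:
    rec = {"package_version": PACKAGE_VERSION, "seed": seed,
           "model_config": config.to_dict()}
    if extra:
        rec.update(extra)
    return rec
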