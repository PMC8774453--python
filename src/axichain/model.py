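"""Model / Results front end.

``AxialPatternModel`` bundles a chain geometry with the target patterns it is
asked to develop; ``fit`` runs the backpropagation-through-time search and
returns an ``AxialPatternResults`` carrying the trained genome, the loss
history and diagnostics. Simulation, the perturbation assays and the causal
network analysis all hang off the results object, so a session reads

    >>> model = AxialPatternModel()                # 12-cell reference chain
    >>> res = model.fit(seed=3, iterations=2000)   # doctest: +SKIP
    >>> print(res.summary())                       # doctest: +SKIP
    >>> res.develop().scores                       # doctest: +SKIP

A results object can also be rehydrated from a serialized genome with
``AxialPatternResults.from_params`` (no refit needed).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .config import ModelConfig, default_config
from .params import Parameters, init_parameters
from .state import init_state
from .dynamics import simulate
from .objectives import TargetSpec, pattern_loss
from .training import (Hyperparameters, TrainingRun, train_model,
                       train_ensemble, random_baseline, satisfying_fraction)
from . import experiments as _exp
from . import causal as _causal


class AxialPatternModel:
    """A bounded chain of cells with shared intracellular controllers, posed
    the bounded-axial-patterning problem (gradient activity target plus
    boundary-marker target)."""

    def __init__(self, config: ModelConfig | None = None,
                 targets: TargetSpec | None = None):
        self.config = config if config is not None else default_config()
        self.targets = targets if targets is not None \
            else TargetSpec.for_cells(self.config.n_cells)

    @classmethod
    def from_config(cls, **config_fields) -> "AxialPatternModel":
        return cls(config=ModelConfig(**config_fields))

    def fit(self, seed: int = 0, hyper: Hyperparameters | None = None,
            progress: bool = False, **hyper_overrides) -> "AxialPatternResults":
        """BPTT parameter search from a seeded random genome."""
        if hyper is None:
            hyper = Hyperparameters(**hyper_overrides)
        elif hyper_overrides:
            hyper = replace(hyper, **hyper_overrides)
        run = train_model(self.config, hyper, seed, targets=self.targets,
                          progress=progress)
        return AxialPatternResults(self, run.final_params, run=run)

    def fit_ensemble(self, n_models: int, base_seed: int = 0,
                     hyper: Hyperparameters | None = None,
                     progress: bool = False,
                     **hyper_overrides) -> list["AxialPatternResults"]:
        if hyper is None:
            hyper = Hyperparameters(**hyper_overrides)
        elif hyper_overrides:
            hyper = replace(hyper, **hyper_overrides)
        runs = train_ensemble(self.config, hyper, n_models, base_seed,
                              targets=self.targets, progress=progress)
        return [AxialPatternResults(self, r.final_params, run=r)
                for r in runs]

    def random_baseline(self, k: int = 100, seed: int = 0,
                        horizon: int | None = None) -> np.ndarray:
        """Pattern losses of k untrained random genomes (the null against
        which training is judged)."""
        return random_baseline(self.config, k, seed, targets=self.targets,
                               horizon=horizon)

    def random_results(self, seed: int = 0) -> "AxialPatternResults":
        """Results wrapper around an untrained random genome."""
        return AxialPatternResults(self, init_parameters(seed, self.config))

    @staticmethod
    def satisfying_fraction(results, threshold: float | None = None) -> float:
        runs = [r.run for r in results if r.run is not None]
        return satisfying_fraction(runs, threshold)


class AxialPatternResults:
    """A parameterized chain: the genome plus everything one asks of it."""

    def __init__(self, model: AxialPatternModel, params: Parameters,
                 run: TrainingRun | None = None):
        self.model = model
        self.params = params
        self.run = run

    # -- construction ----------------------------------------------------

    @classmethod
    def from_params(cls, params: Parameters,
                    config: ModelConfig | None = None) -> "AxialPatternResults":
        return cls(AxialPatternModel(config=config), params)

    @classmethod
    def from_json(cls, path, config: ModelConfig | None = None
                  ) -> "AxialPatternResults":
        return cls.from_params(Parameters.from_json(path), config=config)

    # -- fit quality -----------------------------------------------------

    @property
    def config(self) -> ModelConfig:
        return self.model.config

    def loss(self, horizon: int | None = None, window: int = 100) -> float:
        """Pattern loss of a fresh rollout from the all-zero state."""
        if horizon is None:
            horizon = self.config.default_horizon
        traj = simulate(init_state(self.config), self.params, self.config,
                        horizon)
        return float(pattern_loss(traj, self.model.targets, window=window))

    def summary(self) -> str:
        dev = self.develop()
        lines = [
            "Axial patterning fit",
            "=" * 54,
            f"cells: {self.config.n_cells:>4d}   junctions: "
            f"{self.config.n_junctions}   dt: {self.config.dt}",
            f"horizon: {self.config.default_horizon} steps "
            f"({self.config.default_horizon * self.config.dt:.0f} sim-seconds)",
        ]
        if self.run is not None:
            lines += [
                f"seed: {self.run.seed}   iterations: "
                f"{self.run.hyper.iterations}   optimizer: Adam "
                f"(lr={self.run.hyper.learning_rate}, "
                f"clip={self.run.hyper.clip_norm})",
                f"final loss: {self.run.final_loss:.5f}   satisfying "
                f"(<= {self.run.hyper.satisfying_threshold}): "
                f"{self.run.satisfying}",
            ]
        lines += [
            "-" * 54,
            f"activity match:  {dev.scores['activity_match']:6.1f} %",
            f"boundary match:  {dev.scores['boundary_match']:6.1f} %",
            "=" * 54,
        ]
        return "\n".join(lines)

    # -- simulation and assays -------------------------------------------

    def simulate(self, n_steps: int | None = None, state=None):
        if n_steps is None:
            n_steps = self.config.default_horizon
        if state is None:
            state = init_state(self.config)
        return simulate(state, self.params, self.config, n_steps)

    def develop(self, horizon: int | None = None):
        return _exp.develop_homogeneous(self.params, self.config,
                                        horizon=horizon)

    def regenerate(self, horizon: int | None = None):
        return _exp.regenerate_from_fragment(self.params, self.config,
                                             horizon=horizon)

    def rescale(self, new_n: int, horizon: int | None = None):
        return _exp.rescale_develop(self.params, self.config, new_n,
                                    horizon=horizon)

    def random_ic_ensemble(self, count: int = 1000, seed: int = 0,
                           horizon: int | None = None):
        return _exp.random_ic_ensemble(self.params, self.config, count=count,
                                       seed=seed, horizon=horizon)

    def clamp_sweep(self, values=None, horizon: int = 2000):
        return _exp.clamp_sweep(self.params, values=values, horizon=horizon)

    def controller_patterns(self, horizon: int | None = None):
        return _exp.controller_pattern_summary(self.simulate(horizon))

    # -- causal analysis -------------------------------------------------

    def causal_tensor(self, tau: int, source_var: str = "r",
                      target_var: str = "s", init_state_=None):
        return _causal.causal_jacobian(self.params, init_state_, tau,
                                       source_var=source_var,
                                       target_var=target_var,
                                       config=self.config)

    def causal_network(self, tau: int, source_var: str = "r",
                       target_var: str = "s", rule: str = "tukey",
                       init_state_=None):
        tensor = self.causal_tensor(tau, source_var=source_var,
                                    target_var=target_var,
                                    init_state_=init_state_)
        return _causal.extract_causal_network(tensor, rule=rule)

    # -- persistence -----------------------------------------------------

    def save_params(self, path, provenance: dict | None = None) -> None:
        prov = {"model_config": self.config.to_dict()}
        if self.run is not None:
            prov.update(seed=self.run.seed,
                        iterations=self.run.hyper.iterations,
                        final_loss=self.run.final_loss)
        if provenance:
            prov.update(provenance)
        self.params.to_json(path, provenance=prov)
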