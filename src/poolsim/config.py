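"""Configuration objects for the simulation framework.

Two levels of configuration exist:

* :class:`SimulationConfig` — the generative model for one two-class
  expression dataset (class sizes, feature counts, effect sizes, noise).
* :class:`RunConfig` — a full benchmarking run: the grid of scenarios,
  technical-noise levels, pool sizes and classification methods, plus
  repetition count, seeding and output options.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

#: Scenario tags for the informative part of the simulated matrix.
DE_ONLY = "de_only"            # independent differentially expressed genes
LINEAR_ONLY = "linear_only"    # bivariate linear patterns
COMBINED = "combined"          # both
SCENARIOS = (DE_ONLY, LINEAR_ONLY, COMBINED)

#: Classification method tags.
SVML = "svml"
SVMR = "svmr"
RF = "rf"
PPLSDA = "pplsda"
TTEST_LDA = "ttest_lda"
METHODS = (SVML, SVMR, RF, PPLSDA, TTEST_LDA)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one two-class log2-expression dataset.

    The defaults reproduce the reference setting: 30 subjects per class,
    1000 features, background N(8, 0.2^2), ten differentially expressed
    genes with per-gene shift Delta ~ U[0.1, 0.5], ten bivariate linear
    patterns with class offset delta = 0.4, and technical noise with
    standard deviation 0.2 or 0.4 on the log2 scale.
    """

    n_per_class: int = 30
    n_features: int = 1000
    n_de_genes: int = 10
    n_patterns: int = 10
    background_mean: float = 8.0
    bio_sd: float = 0.2
    noise_sd: float = 0.2
    de_delta_interval: tuple[float, float] = (0.1, 0.5)
    pattern_offset: float = 0.4
    class_mean_interval: tuple[float, float] = (6.0, 10.0)
    scenario: str = DE_ONLY
    seed: int | None = None
    #: shuffle informative columns into random positions (robustness checks)
    shuffle_columns: bool = False
    #: evaluate on measured (noisy) test samples instead of their
    #: biological values; the reference protocol classifies noise-free
    #: single samples, so technical noise enters through training only
    test_noise: bool = False

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be at least 2")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if self.bio_sd <= 0:
            raise ValueError("bio_sd must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.de_delta_interval
        if lo < 0 or hi < lo:
            raise ValueError("de_delta_interval must satisfy 0 <= lower <= upper")
        lo, hi = self.class_mean_interval
        if hi < lo:
            raise ValueError("class_mean_interval must be ordered")
        if self.n_informative > self.n_features:
            raise ValueError(
                f"informative columns ({self.n_informative}) exceed "
                f"n_features ({self.n_features})"
            )

    @property
    def n_samples(self) -> int:
        return 2 * self.n_per_class

    @property
    def n_informative(self) -> int:
        """Number of informative (non-background) columns for the scenario."""
        n = 0
        if self.scenario in (DE_ONLY, COMBINED):
            n += self.n_de_genes
        if self.scenario in (LINEAR_ONLY, COMBINED):
            n += 2 * self.n_patterns
        return n

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters of the five classification methods.

    Defaults follow the benchmark setting: SVM cost 1, radial-kernel
    gamma tuned by inner 10-fold CV on a logarithmic grid around the
    1/n_features heuristic, random forests with 1000 trees and 20
    candidate variables per split, PPLS-DA with power parameter in
    [0, 1] and inner 10-fold CV for the number of components, and a
    pooled-variance t-test selecting the ten best candidates for LDA.
    """

    svm_cost: float = 1.0
    #: exponents of 2 for the gamma grid, scaled by 1/n_features at fit time
    gamma_grid_log2: tuple[int, ...] = tuple(range(-10, 3))
    n_trees: int = 1000
    mtry: int = 20
    n_select: int = 10
    equal_var: bool = True      # pooled-variance t-test; False -> Welch
    max_components: int = 10
    power_bounds: tuple[float, float] = (0.0, 1.0)
    n_power: int = 21
    inner_cv: int = 10


@dataclass
class RunConfig:
    """A full experiment: simulation settings plus the evaluation grid."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    scenarios: tuple[str, ...] = SCENARIOS
    noise_sds: tuple[float, ...] = (0.2, 0.4)
    pool_sizes: tuple[int, ...] = (1, 2, 3, 5)
    methods: tuple[str, ...] = METHODS
    n_reps: int = 500
    base_seed: int = 0
    n_jobs: int = 1
    bootstrap_level: float = 0.95
    n_boot: int = 1000
    out_dir: str | None = None
    paired: bool = True

    def __post_init__(self) -> None:
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario tag {s!r}")
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method tag {m!r}")
        for m_p in self.pool_sizes:
            if m_p < 1 or self.simulation.n_per_class % m_p:
                raise ValueError(
                    f"pool size {m_p} does not divide the class size "
                    f"{self.simulation.n_per_class}"
                )
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        if not 0 < self.bootstrap_level < 1:
            raise ValueError("bootstrap_level must lie in (0, 1)")


_SIM_KEYS = {f.name for f in fields(SimulationConfig)} - {"scenario", "noise_sd"}
_CLF_KEYS = {f.name for f in fields(ClassifierConfig)}
_RUN_KEYS = {f.name for f in fields(RunConfig)} - {"simulation", "classifier"}


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file.

    Top-level keys may be any :class:`RunConfig` field, any
    :class:`SimulationConfig` field (except ``scenario``/``noise_sd``,
    which are grid axes), or a ``classifier`` mapping.  An empty file
    yields the all-defaults configuration.  Unknown keys raise a
    ``ValueError`` listing them.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    unknown = set(raw) - _RUN_KEYS - _SIM_KEYS - {"classifier"}
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    clf_raw = dict(raw.get("classifier") or {})
    unknown = set(clf_raw) - _CLF_KEYS
    if unknown:
        raise ValueError(f"unknown classifier keys: {sorted(unknown)}")
    for key in ("gamma_grid_log2", "power_bounds"):
        if key in clf_raw:
            clf_raw[key] = tuple(clf_raw[key])
    sim_raw = {k: raw[k] for k in raw if k in _SIM_KEYS}
    for key in ("de_delta_interval", "class_mean_interval"):
        if key in sim_raw:
            sim_raw[key] = tuple(sim_raw[key])
    run_raw = {k: raw[k] for k in raw if k in _RUN_KEYS}
    for key in ("scenarios", "noise_sds", "pool_sizes", "methods"):
        if key in run_raw:
            run_raw[key] = tuple(run_raw[key])
    return RunConfig(
        simulation=SimulationConfig(**sim_raw),
        classifier=ClassifierConfig(**clf_raw),
        **run_raw,
    )
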