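"""Two-class log2-scale gene-expression data generator.

The generative model separates biological values ``X`` from measured
values ``Y = X + eps``, where ``eps`` is i.i.d. additive technical noise
on the log2 scale (one draw per hybridised array and gene).

Three scenarios populate the informative leading columns of the matrix:

* ``de_only`` — ten independent differentially expressed genes.  For
  gene *g*, the class-A mean ``mu_A`` is drawn uniformly from [6, 10]
  and class B is shifted by ``Delta_g ~ U[0.1, 0.5]``; both classes
  share the biological standard deviation ``sigma = 0.2``.
* ``linear_only`` — ten bivariate linear patterns.  The first gene g1
  of a pattern has a common mean for both classes; the second gene is
  ``g2 = 2 * g1`` for class A and ``g2 = 2 * g1 + delta`` (delta = 0.4)
  for class B, exactly on the biological scale.  The pattern therefore
  also induces a marginal mean difference of ``delta`` on g2.
* ``combined`` — both blocks.

Within one repetition of the benchmark, the training and the test set
are drawn *under the same conditions*: the per-gene means, effect sizes
and pattern pairings (:class:`ScenarioParams`) are realised once and
shared, while the biological values and the technical noise are fresh.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import COMBINED, DE_ONLY, LINEAR_ONLY, SimulationConfig

CLASS_A = "A"
CLASS_B = "B"

ROLE_BACKGROUND = "background"
ROLE_DE = "de"
ROLE_PATTERN_G1 = "pattern_g1"
ROLE_PATTERN_G2 = "pattern_g2"


@dataclass(frozen=True)
class ScenarioParams:
    """Realised gene-level parameters shared by train and test sets.

    ``de_means``/``de_deltas`` hold mu_A and Delta per DE gene;
    ``pattern_means`` holds the common g1 mean per linear pattern.
    Arrays are empty when the scenario lacks the corresponding block.
    """

    de_means: np.ndarray
    de_deltas: np.ndarray
    pattern_means: np.ndarray


def draw_scenario_params(cfg: SimulationConfig, rng: np.random.Generator) -> ScenarioParams:
    """Draw the per-repetition gene-level parameters for ``cfg.scenario``."""
    lo_m, hi_m = cfg.class_mean_interval
    lo_d, hi_d = cfg.de_delta_interval
    n_de = cfg.n_de_genes if cfg.scenario in (DE_ONLY, COMBINED) else 0
    n_pat = cfg.n_patterns if cfg.scenario in (LINEAR_ONLY, COMBINED) else 0
    return ScenarioParams(
        de_means=rng.uniform(lo_m, hi_m, size=n_de),
        de_deltas=rng.uniform(lo_d, hi_d, size=n_de),
        pattern_means=rng.uniform(lo_m, hi_m, size=n_pat),
    )


def draw_background(
    n_samples: int, n_cols: int, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Non-informative biological values: i.i.d. N(background_mean, bio_sd^2)."""
    if n_samples < 1 or n_cols < 1:
        raise ValueError("n_samples and n_cols must be positive")
    return rng.normal(cfg.background_mean, cfg.bio_sd, size=(n_samples, n_cols))


def simulate_de_block(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    params: ScenarioParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Biological values for the independently differentially expressed genes.

    Returns the ``(2 n_per_class, n_de_genes)`` matrix (class A rows first)
    and the realised per-gene shifts Delta.
    """
    if params is None or params.de_means.size == 0:
        lo_m, hi_m = cfg.class_mean_interval
        lo_d, hi_d = cfg.de_delta_interval
        mu_a = rng.uniform(lo_m, hi_m, size=cfg.n_de_genes)
        delta = rng.uniform(lo_d, hi_d, size=cfg.n_de_genes)
    else:
        mu_a, delta = params.de_means, params.de_deltas
    n = cfg.n_per_class
    block_a = rng.normal(mu_a, cfg.bio_sd, size=(n, mu_a.size))
    block_b = rng.normal(mu_a + delta, cfg.bio_sd, size=(n, mu_a.size))
    return np.vstack([block_a, block_b]), delta


def simulate_pattern_block(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    params: ScenarioParams | None = None,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Biological values for the bivariate linear patterns.

    Columns are arranged g1, g2 adjacently per pattern; the returned
    pairing lists (g1, g2) column indices within the block.  The linear
    relations g2 = 2*g1 (class A) and g2 = 2*g1 + delta (class B) hold
    exactly on the biological values; technical noise is added later.
    """
    if params is None or params.pattern_means.size == 0:
        lo_m, hi_m = cfg.class_mean_interval
        mu = rng.uniform(lo_m, hi_m, size=cfg.n_patterns)
    else:
        mu = params.pattern_means
    n = cfg.n_per_class
    g1 = rng.normal(mu, cfg.bio_sd, size=(2 * n, mu.size))
    g2 = 2.0 * g1
    g2[n:, :] += cfg.pattern_offset
    block = np.empty((2 * n, 2 * mu.size))
    block[:, 0::2] = g1
    block[:, 1::2] = g2
    pairing = [(2 * k, 2 * k + 1) for k in range(mu.size)]
    return block, pairing


def add_technical_noise(
    X: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Measured values Y = X + eps, eps i.i.d. N(0, noise_sd^2)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0:
        return X.copy()
    return X + rng.normal(0.0, noise_sd, size=X.shape)


@dataclass
class ExpressionDataset:
    """A simulated two-class expression dataset.

    ``X`` holds biological log2 values, ``Y`` the measured values
    (``X`` plus technical noise), both of shape (samples, features) with
    class-A rows first.  ``truth`` annotates each feature column with its
    role, the realised Delta for DE genes, the class offset delta and
    pattern pairing for linear-pattern genes.
    """

    X: np.ndarray
    Y: np.ndarray
    labels: np.ndarray
    truth: pd.DataFrame
    config: SimulationConfig | None = None
    params: ScenarioParams | None = None

    def __post_init__(self) -> None:
        if self.X.shape != self.Y.shape:
            raise ValueError("X and Y must have identical shape")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("labels length must match the number of rows")
        if len(self.truth) != self.X.shape[1]:
            raise ValueError("truth must annotate every feature column")

    @property
    def feature_ids(self) -> np.ndarray:
        return self.truth["feature"].to_numpy()

    @property
    def sample_ids(self) -> np.ndarray:
        counts = {}
        ids = []
        for lab in self.labels:
            counts[lab] = counts.get(lab, 0) + 1
            ids.append(f"{lab}{counts[lab]:02d}")
        return np.asarray(ids)


def _build_truth(cfg: SimulationConfig, params: ScenarioParams) -> pd.DataFrame:
    roles: list[str] = []
    deltas: list[float] = []
    patterns: list[float] = []
    if cfg.scenario in (DE_ONLY, COMBINED):
        roles += [ROLE_DE] * cfg.n_de_genes
        deltas += list(params.de_deltas)
        patterns += [np.nan] * cfg.n_de_genes
    if cfg.scenario in (LINEAR_ONLY, COMBINED):
        for k in range(cfg.n_patterns):
            roles += [ROLE_PATTERN_G1, ROLE_PATTERN_G2]
            deltas += [np.nan, cfg.pattern_offset]
            patterns += [k, k]
    n_bg = cfg.n_features - len(roles)
    roles += [ROLE_BACKGROUND] * n_bg
    deltas += [np.nan] * n_bg
    patterns += [np.nan] * n_bg
    width = len(str(cfg.n_features))
    return pd.DataFrame(
        {
            "feature": [f"g{i + 1:0{width}d}" for i in range(cfg.n_features)],
            "role": roles,
            "delta": deltas,
            "pattern": patterns,
        }
    )


def sample_biological(
    cfg: SimulationConfig, params: ScenarioParams, rng: np.random.Generator
) -> np.ndarray:
    """One biological matrix given realised gene-level parameters."""
    blocks = []
    if cfg.scenario in (DE_ONLY, COMBINED):
        blocks.append(simulate_de_block(cfg, rng, params)[0])
    if cfg.scenario in (LINEAR_ONLY, COMBINED):
        blocks.append(simulate_pattern_block(cfg, rng, params)[0])
    n_info = sum(b.shape[1] for b in blocks)
    if n_info < cfg.n_features:
        blocks.append(draw_background(cfg.n_samples, cfg.n_features - n_info, cfg, rng))
    return np.hstack(blocks)


def sample_dataset(
    cfg: SimulationConfig, params: ScenarioParams, rng: np.random.Generator
) -> ExpressionDataset:
    """One dataset (biological + measured) under given realised parameters."""
    X = sample_biological(cfg, params, rng)
    Y = add_technical_noise(X, cfg.noise_sd, rng)
    labels = np.array([CLASS_A] * cfg.n_per_class + [CLASS_B] * cfg.n_per_class)
    truth = _build_truth(cfg, params)
    if cfg.shuffle_columns:
        order = rng.permutation(cfg.n_features)
        X = X[:, order]
        Y = Y[:, order]
        truth = truth.iloc[order].reset_index(drop=True)
    return ExpressionDataset(X=X, Y=Y, labels=labels, truth=truth, config=cfg, params=params)


def assemble_dataset(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> ExpressionDataset:
    """Draw gene-level parameters and one full dataset for ``cfg``.

    With ``rng`` omitted, the stream is seeded from ``cfg.seed``, so an
    identical configuration yields a bit-identical dataset.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    params = draw_scenario_params(cfg, rng)
    return sample_dataset(cfg, params, rng)


# ---------------------------------------------------------------------------
# Delimited-text serialisation (15 significant digits, lossless round trip)

_FMT = "%.15g"


def write_matrix(path: str | Path, values: np.ndarray, feature_ids, sample_ids) -> None:
    df = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample"), columns=feature_ids)
    df.to_csv(path, sep="\t", float_format=_FMT)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_dataset(ds: ExpressionDataset, directory: str | Path, stem: str = "dataset") -> dict:
    """Write measured/biological matrices, labels and truth as TSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / f"{stem}.expression.tsv",
        "biological": directory / f"{stem}.biological.tsv",
        "labels": directory / f"{stem}.labels.tsv",
        "truth": directory / f"{stem}.truth.tsv",
    }
    sample_ids = ds.sample_ids
    write_matrix(paths["expression"], ds.Y, ds.feature_ids, sample_ids)
    write_matrix(paths["biological"], ds.X, ds.feature_ids, sample_ids)
    pd.DataFrame({"sample": sample_ids, "class": ds.labels}).to_csv(
        paths["labels"], sep="\t", index=False
    )
    ds.truth.to_csv(paths["truth"], sep="\t", index=False, float_format=_FMT)
    return paths


def read_dataset(directory: str | Path, stem: str = "dataset") -> ExpressionDataset:
    directory = Path(directory)
    expr = read_matrix(directory / f"{stem}.expression.tsv")
    bio = read_matrix(directory / f"{stem}.biological.tsv")
    labels = pd.read_csv(directory / f"{stem}.labels.tsv", sep="\t")["class"].to_numpy()
    truth = pd.read_csv(directory / f"{stem}.truth.tsv", sep="\t")
    return ExpressionDataset(
        X=bio.to_numpy(), Y=expr.to_numpy(), labels=labels, truth=truth
    )
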