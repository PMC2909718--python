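"""Ideal raw-scale pooling of log2 expression values.

A pool of size ``m_p`` mixes equal amounts of RNA from ``m_p`` subjects
of the same class, so the ideal pooled expression is the arithmetic mean
on the raw scale.  Values simulated on the log2 scale are therefore
exponentiated (base 2), averaged within the pool, and re-logged:

    pooled = log2( mean_i 2**x_i )

By Jensen's inequality (2**x is convex) the pooled log2 value is at
least the mean of the member log2 values, with equality only for
constant pools.  Each pool is hybridised on one array, so a single
technical-noise draw is added per pool and gene after averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ExpressionDataset


@dataclass(frozen=True)
class PoolAssignment:
    """Partition of each class's samples into equally sized pools.

    ``pools`` lists ``(pool_id, class_label, member_row_indices)`` in
    pool-id order; every sample belongs to exactly one pool and pools
    never mix classes.
    """

    pool_size: int
    pools: tuple[tuple[int, str, tuple[int, ...]], ...]
    n_pools_per_class: int

    def __post_init__(self) -> None:
        members = [i for _, _, ms in self.pools for i in ms]
        if len(members) != len(set(members)):
            raise ValueError("a sample appears in more than one pool")
        for _, _, ms in self.pools:
            if len(ms) != self.pool_size:
                raise ValueError("every pool must have exactly pool_size members")

    @property
    def labels(self) -> np.ndarray:
        return np.array([cls for _, cls, _ in self.pools])

    @property
    def n_samples(self) -> int:
        return self.pool_size * len(self.pools)


def assign_pools(
    labels: np.ndarray, m_p: int, rng: np.random.Generator
) -> PoolAssignment:
    """Randomly partition each class's samples into pools of size ``m_p``.

    Members are drawn without replacement and each sample contributes to
    exactly one pool; ``m_p = 1`` is the identity (single-sample) design.
    """
    labels = np.asarray(labels)
    if m_p < 1:
        raise ValueError("pool size must be at least 1")
    pools: list[tuple[int, str, tuple[int, ...]]] = []
    pool_id = 0
    for cls in pd.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) % m_p:
            raise ValueError(
                f"pool size {m_p} does not divide the class size {len(idx)}"
            )
        idx = rng.permutation(idx)
        for start in range(0, len(idx), m_p):
            pools.append((pool_id, str(cls), tuple(int(i) for i in idx[start:start + m_p])))
            pool_id += 1
    n_pools = len(pools) // len(pd.unique(labels))
    return PoolAssignment(pool_size=m_p, pools=tuple(pools), n_pools_per_class=n_pools)


def pool_expression(X: np.ndarray, assignment: PoolAssignment) -> np.ndarray:
    """Pool log2 values on the raw scale: ``log2(mean(2**x))`` per pool."""
    X = np.asarray(X)
    n_rows = X.shape[0]
    for _, _, members in assignment.pools:
        if any(i < 0 or i >= n_rows for i in members):
            raise ValueError("pool member index out of range")
    pooled = np.empty((len(assignment.pools), X.shape[1]))
    raw = np.exp2(X)
    for row, (_, _, members) in enumerate(assignment.pools):
        pooled[row] = np.log2(raw[list(members)].mean(axis=0))
    return pooled


def make_pooled_training_set(
    ds: ExpressionDataset, m_p: int, noise_sd: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, PoolAssignment]:
    """Measured training matrix for a pooling design of size ``m_p``.

    Pools are formed from the *biological* matrix ``ds.X`` (RNA is mixed
    before hybridisation), then one technical-noise draw per pool and
    gene is added — one array per pool.  ``m_p = 1`` reproduces the
    single-sample measured design.  Returns the pooled measured matrix,
    the pool class labels, and the assignment.
    """
    assignment = assign_pools(ds.labels, m_p, rng)
    pooled = pool_expression(ds.X, assignment)
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 0:
        pooled = pooled + rng.normal(0.0, noise_sd, size=pooled.shape)
    return pooled, assignment.labels, assignment


def design_variance(
    sigma: float, sigma_eps: float, n: int, m_p: int
) -> tuple[float, float]:
    """Variance of the class mean under the two designs at equal subject count.

    Single-sample design: ``(sigma^2 + sigma_eps^2) / n``.
    Pooling design with ``n_P = n / m_p`` pools of size ``m_p``:
    ``(sigma^2 / m_p + sigma_eps^2) / n_P``.  With ``sigma_eps = 0`` both
    equal ``sigma^2 / n``; with technical noise the pooled design has the
    *larger* variance of the estimated mean because fewer arrays average
    fewer noise draws.
    """
    if sigma < 0 or sigma_eps < 0:
        raise ValueError("standard deviations must be non-negative")
    if m_p < 1 or n % m_p:
        raise ValueError(f"pool size {m_p} does not divide n = {n}")
    n_pools = n // m_p
    var_single = (sigma**2 + sigma_eps**2) / n
    var_pooled = (sigma**2 / m_p + sigma_eps**2) / n_pools
    return var_single, var_pooled


def write_assignment(path: str | Path, assignment: PoolAssignment, sample_ids=None) -> None:
    rows = []
    for pool_id, _, members in assignment.pools:
        for i in members:
            sid = sample_ids[i] if sample_ids is not None else i
            rows.append({"sample": sid, "pool": pool_id})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
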