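"""Unsupervised radiomic-signature construction.

The feature matrix (patients x features) is reduced in three steps, all
blinded to outcome:

1. greedy correlation pruning at |Pearson r| > 0.8;
2. consensus hierarchical clustering of the *features*: repeatedly subsample
   80% of the features, cluster them (1 - Pearson correlation distance,
   average linkage), and record how often each feature pair lands in the
   same cluster, yielding a consensus matrix per candidate k;
3. pick k from the relative change in the area under the consensus-matrix
   CDF, and take each cluster's medoid (the member minimizing total
   Euclidean distance to the others, on z-scored columns) as the cluster's
   representative feature.

The representatives form the radiomic signature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ConsensusResult",
    "RadiomicSignature",
    "prune_correlated",
    "consensus_cluster",
    "select_k",
    "cluster_medoids",
    "build_signature",
]

logger = logging.getLogger(__name__)

DEFAULT_K_RANGE = (2, 3, 4, 5, 6)
DEFAULT_N_RESAMPLES = 500
DEFAULT_SUBSAMPLE_FRACTION = 0.8
DEFAULT_ELBOW_FRACTION = 0.25


@dataclass
class ConsensusResult:
    """Per-k consensus matrices and the CDF-area diagnostics used to pick k."""

    k_range: tuple[int, ...]
    consensus: dict[int, np.ndarray]  # k -> features x features matrix
    feature_names: list[str]
    cdf_area: dict[int, float] = field(default_factory=dict)
    delta_area: dict[int, float] = field(default_factory=dict)
    chosen_k: int | None = None
    assignments: dict[int, np.ndarray] = field(default_factory=dict)  # k -> labels 1..k


@dataclass
class RadiomicSignature:
    """Representative (medoid) feature per cluster, with per-patient values."""

    feature_names: list[str]
    cluster_ids: list[int]
    values: pd.DataFrame  # patients x representative features


def _correlation_matrix(df: pd.DataFrame) -> np.ndarray:
    """|corr| with NaNs (constant columns) treated as 0, diagonal zeroed."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    return np.abs(corr)


def prune_correlated(df: pd.DataFrame, threshold: float = 0.8) -> pd.DataFrame:
    """Greedily drop features until no pair has |Pearson r| > threshold.

    At each step the feature with the highest mean |r| over its currently
    violating partners is dropped (ties broken by feature name), which
    preferentially removes hub features.  Constant columns have undefined
    correlations and are treated as uncorrelated (kept, logged).
    """
    if df.shape[1] < 2:
        return df.copy()
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        logger.info("constant features treated as uncorrelated: %s", constant[:5])
    names = np.asarray(df.columns)
    corr = _correlation_matrix(df)
    alive = np.ones(len(names), dtype=bool)
    removed: list[tuple[str, str]] = []
    while True:
        viol = (corr > threshold) & np.outer(alive, alive)
        if not viol.any():
            break
        n_viol = viol.sum(axis=1)
        mean_viol = np.where(n_viol > 0, (corr * viol).sum(axis=1) / np.maximum(n_viol, 1), -1.0)
        candidates = np.flatnonzero(n_viol > 0)
        best = max(mean_viol[candidates])
        tied = candidates[mean_viol[candidates] == best]
        drop = tied[np.argsort(names[tied])[0]]
        partner = int(np.argmax(corr[drop] * viol[drop]))
        removed.append((str(names[drop]), str(names[partner])))
        alive[drop] = False
    if removed:
        logger.info("pruned %d correlated features", len(removed))
    survivors = names[alive]
    out = df.loc[:, survivors].copy()
    out.attrs["pruned"] = removed
    return out


def _feature_distance(x: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson r distance between columns of x."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    return squareform(dist, checks=False)


def consensus_cluster(
    df: pd.DataFrame,
    k_range: tuple[int, ...] = DEFAULT_K_RANGE,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    subsample_fraction: float = DEFAULT_SUBSAMPLE_FRACTION,
    seed: int | np.random.Generator = 0,
) -> ConsensusResult:
    """Consensus matrices over feature subsamples, for each candidate k.

    Each resample draws ``ceil(subsample_fraction * n_features)`` features
    without replacement, builds one average-linkage dendrogram on the
    1 - Pearson distance between feature columns, and cuts it at every k in
    ``k_range``.  The consensus entry M_k(i, j) is the fraction of resamples
    containing both i and j in which they co-clustered (0 when never
    co-sampled).  Final per-k assignments come from average-linkage
    clustering of 1 - M_k, as is conventional for consensus clustering.
    """
    n_features = df.shape[1]
    k_range = tuple(sorted(set(int(k) for k in k_range)))
    if n_resamples < 10:
        raise ValueError("need at least 10 resamples")
    if n_features < max(k_range) + 1:
        raise ValueError("need more features than the largest k")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = df.to_numpy(dtype=float)
    m = int(np.ceil(subsample_fraction * n_features))

    co_sampled = np.zeros((n_features, n_features))
    co_clustered = {k: np.zeros((n_features, n_features)) for k in k_range}
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n_features, size=m, replace=False))
        if m <= max(k_range):
            logger.warning("subsample smaller than largest k; resample skipped")
            continue
        z = linkage(_feature_distance(x[:, idx]), method="average")
        co_sampled[np.ix_(idx, idx)] += 1.0
        for k in k_range:
            labels = fcluster(z, t=k, criterion="maxclust")
            for lab in np.unique(labels):
                members = idx[labels == lab]
                co_clustered[k][np.ix_(members, members)] += 1.0

    consensus = {}
    for k in k_range:
        with np.errstate(invalid="ignore", divide="ignore"):
            mk = np.where(co_sampled > 0, co_clustered[k] / co_sampled, 0.0)
        np.fill_diagonal(mk, 1.0)
        consensus[k] = mk

    result = ConsensusResult(
        k_range=k_range, consensus=consensus, feature_names=list(df.columns)
    )
    for k in k_range:
        dist = 1.0 - consensus[k]
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(np.clip(dist, 0.0, None), checks=False), method="average")
        result.assignments[k] = fcluster(z, t=k, criterion="maxclust")
    return result


def _cdf_area(mk: np.ndarray, grid_size: int = 101) -> float:
    """Area under the empirical CDF of the upper-triangle consensus entries."""
    vals = mk[np.triu_indices_from(mk, k=1)]
    grid = np.linspace(0.0, 1.0, grid_size)
    cdf = np.searchsorted(np.sort(vals), grid, side="right") / vals.size
    return float(np.trapezoid(cdf, grid))


def select_k(
    result: ConsensusResult, elbow_fraction: float = DEFAULT_ELBOW_FRACTION
) -> int:
    """Choose k from the relative change of the consensus-CDF area.

    A(k) is the area under the CDF of consensus values at k; the relative
    change is Delta(2) = A(2) and Delta(k) = (A(k) - A(k-1)) / A(k-1) for
    k > 2.  The chosen k is the largest k whose Delta(k) still reaches
    ``elbow_fraction`` of the maximum Delta — the deterministic version of
    reading the elbow where further splits stop improving separability.
    """
    ks = result.k_range
    if len(ks) < 3:
        raise ValueError("need at least three k values to locate an elbow")
    areas = {k: _cdf_area(result.consensus[k]) for k in ks}
    deltas: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            deltas[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else 0.0
    if any(d < 0 for d in deltas.values()):
        logger.warning("non-monotone consensus CDF areas: %s", areas)
    max_delta = max(deltas.values())
    if max_delta <= 0:
        logger.warning("flat CDF-area curve; defaulting to smallest k")
        chosen = ks[0]
    else:
        eligible = [k for k in ks if deltas[k] >= elbow_fraction * max_delta]
        chosen = max(eligible)
        if chosen == ks[-1] and len(eligible) == len(ks):
            logger.warning("relative change never drops below the elbow; returning max k")
    result.cdf_area = areas
    result.delta_area = deltas
    result.chosen_k = chosen
    return chosen


def cluster_medoids(
    df: pd.DataFrame,
    assignments: np.ndarray,
    method: str = "euclidean",
) -> RadiomicSignature:
    """One representative feature per cluster.

    ``method='euclidean'`` (primary): the medoid minimizing the summed
    Euclidean distance to its cluster's members, computed on z-scored
    columns so large-magnitude features do not dominate.
    ``method='correlation'``: the feature with the highest mean pairwise
    Pearson correlation within the cluster.  Ties break lexicographically.
    """
    labels = np.asarray(assignments)
    if labels.shape[0] != df.shape[1]:
        raise ValueError("one assignment per feature required")
    names = np.asarray(df.columns)
    x = df.to_numpy(dtype=float)
    sd = x.std(axis=0)
    z = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    reps: list[tuple[int, str]] = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if members.size == 0:
            raise ValueError(f"cluster {lab} is empty")
        sub = z[:, members]
        if method == "euclidean":
            d2 = (
                (sub**2).sum(axis=0)[:, None]
                + (sub**2).sum(axis=0)[None, :]
                - 2.0 * sub.T @ sub
            )
            cost = np.sqrt(np.clip(d2, 0.0, None)).sum(axis=1)
        elif method == "correlation":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                corr = np.corrcoef(sub, rowvar=False)
            corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))
            cost = -corr.mean(axis=1)  # maximize mean correlation
        else:
            raise ValueError(f"unknown medoid method {method!r}")
        best = cost.min()
        tied = members[cost == best]
        winner = tied[np.argsort(names[tied])[0]]
        reps.append((int(lab), str(names[winner])))

    reps.sort()
    feature_names = [n for _, n in reps]
    return RadiomicSignature(
        feature_names=feature_names,
        cluster_ids=[c for c, _ in reps],
        values=df.loc[:, feature_names].copy(),
    )


def build_signature(
    df: pd.DataFrame,
    prune_threshold: float = 0.8,
    k_range: tuple[int, ...] = DEFAULT_K_RANGE,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    subsample_fraction: float = DEFAULT_SUBSAMPLE_FRACTION,
    elbow_fraction: float = DEFAULT_ELBOW_FRACTION,
    seed: int = 0,
) -> tuple[RadiomicSignature, ConsensusResult, pd.DataFrame]:
    """Pruning -> consensus clustering -> k selection -> medoids, in one call."""
    pruned = prune_correlated(df, prune_threshold)
    result = consensus_cluster(
        pruned, k_range, n_resamples, subsample_fraction, np.random.default_rng(seed)
    )
    k = select_k(result, elbow_fraction)
    signature = cluster_medoids(pruned, result.assignments[k])
    return signature, result, pruned
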