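"""Consensus k-means subtype discovery.

Monti-style consensus clustering: k-means is run on many random subsamples
of the cohort; the consensus index of a sample pair is the fraction of runs
in which they co-clustered, out of the runs that sampled both. Final labels
come from complete-linkage hierarchical clustering of the consensus
dissimilarity (1 - consensus). The number of clusters is chosen from the
empirical CDF of consensus values (the delta-area rule), and samples with
non-positive silhouette width are dropped before downstream analysis.

The similarity between samples is the Pearson correlation of their panel
profiles. k-means is Euclidean-native, so each sample profile is
standardized to zero mean and unit norm, under which squared Euclidean
distance is an increasing function of (1 - Pearson r) and Euclidean k-means
becomes correlation-distance k-means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .preprocessing import ExpressionMatrix
from .survival import logrank

__all__ = [
    "ConsensusParams",
    "ConsensusResult",
    "build_consensus",
    "consensus_cdf_summary",
    "silhouette_filter",
    "survival_k_scan",
]


@dataclass(frozen=True)
class ConsensusParams:
    """Resampling parameters for consensus clustering.

    Defaults mirror the reference procedure (10,000 iterations at a 0.8
    subsampling ratio, correlation distance); desk-scale runs typically use
    a few hundred iterations.
    """

    n_iter: int = 10_000
    subsample_frac: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.subsample_frac <= 1.0:
            raise ValueError("subsample_frac must be in (0, 1]")
        if self.n_iter < 1:
            raise ValueError("n_iter must be positive")


@dataclass(frozen=True)
class ConsensusResult:
    k: int
    sample_ids: tuple[str, ...]
    consensus: np.ndarray
    labels: pd.Series
    silhouette: pd.Series

    def __post_init__(self) -> None:
        c = self.consensus
        if not np.allclose(c, c.T):
            raise ValueError("consensus matrix must be symmetric")
        if c.min() < -1e-12 or c.max() > 1 + 1e-12:
            raise ValueError("consensus entries must lie in [0, 1]")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("consensus diagonal must be 1")

    def offdiag_values(self) -> np.ndarray:
        """Upper-triangle consensus values (the CDF's sample)."""
        iu = np.triu_indices(self.consensus.shape[0], k=1)
        return self.consensus[iu]

    def cdf_area(self) -> float:
        """Exact integral over [0, 1] of the empirical CDF of consensus values."""
        v = np.sort(self.offdiag_values())
        grid = np.unique(np.concatenate(([0.0], v, [1.0])))
        cdf = np.searchsorted(v, grid, side="right") / v.size
        return float(np.sum(np.diff(grid) * cdf[:-1]))


def _standardize_profiles(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-norm rows: Euclidean distance ~ correlation distance."""
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("sample with constant panel profile: correlation undefined")
    return x / norms


def build_consensus(m: ExpressionMatrix, k: int, params: ConsensusParams) -> ConsensusResult:
    """Run consensus k-means at a fixed k.

    consensus[i, j] = (# runs clustering i and j together) / (# runs that
    subsampled both i and j). Final labels cut a complete-linkage tree of
    (1 - consensus) at k; silhouette widths are computed on the same
    consensus dissimilarity.
    """
    n = m.n_samples
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    x = _standardize_profiles(m.values().T)  # samples x genes
    rng = np.random.default_rng(params.seed)
    n_sub = max(k, int(round(params.subsample_frac * n)))

    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(params.n_iter):
        idx = rng.choice(n, size=n_sub, replace=False) if n_sub < n else np.arange(n)
        km = KMeans(n_clusters=k, n_init=1, random_state=int(rng.integers(2**31 - 1)))
        lab = km.fit_predict(x[idx])
        co = (lab[:, None] == lab[None, :]).astype(float)
        ix = np.ix_(idx, idx)
        together[ix] += co
        sampled[ix] += 1.0

    off = ~np.eye(n, dtype=bool)
    if (sampled[off] == 0).any():
        raise ValueError(
            "some sample pairs were never co-subsampled; increase n_iter"
        )
    consensus = np.ones((n, n))
    consensus[off] = together[off] / sampled[off]

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(z, t=k, criterion="maxclust")
    sil = _silhouette_on_dissimilarity(dist, labels)

    sample_ids = tuple(m.sample_ids)
    return ConsensusResult(
        k=k,
        sample_ids=sample_ids,
        consensus=consensus,
        labels=pd.Series(labels, index=list(sample_ids), name="label"),
        silhouette=pd.Series(sil, index=list(sample_ids), name="silhouette"),
    )


def _silhouette_on_dissimilarity(dist: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Silhouette widths s(i) = (b - a) / max(a, b); singletons get 0."""
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    return silhouette_samples(dist, labels, metric="precomputed")


def consensus_cdf_summary(
    results: Sequence[ConsensusResult], delta_threshold: float = 0.15
) -> pd.DataFrame:
    """Area under the consensus CDF per k and the relative delta-area rule.

    delta(k) is the relative increase of the area over the previous k (the
    area itself at the smallest k). The suggested k is the smallest k whose
    following delta falls below ``delta_threshold`` — the point where adding
    clusters stops improving consensus stability appreciably.
    """
    if len(results) < 2:
        raise ValueError("need results for at least two values of k")
    results = sorted(results, key=lambda r: r.k)
    ks = [r.k for r in results]
    if len(set(ks)) != len(ks):
        raise ValueError("duplicate k in results")
    areas = [r.cdf_area() for r in results]
    deltas = [areas[0]]
    for prev, cur in zip(areas, areas[1:]):
        deltas.append((cur - prev) / prev if prev > 0 else cur - prev)
    table = pd.DataFrame({"k": ks, "cdf_area": areas, "delta_area": deltas})

    suggested = ks[-1]
    for i in range(len(ks) - 1):
        if deltas[i + 1] < delta_threshold:
            suggested = ks[i]
            break
    table.attrs["suggested_k"] = int(suggested)
    return table


def silhouette_filter(result: ConsensusResult) -> tuple[list[str], list[str]]:
    """Split samples into (kept, dropped) by positive silhouette width.

    Samples with s(i) <= 0 — including silhouette-zero singletons — are
    dropped from all downstream analyses.
    """
    kept = [s for s in result.sample_ids if result.silhouette[s] > 0]
    dropped = [s for s in result.sample_ids if result.silhouette[s] <= 0]
    return kept, dropped


def survival_k_scan(
    results: Sequence[ConsensusResult],
    clinical: pd.DataFrame,
    time_col: str = "os_years",
    event_col: str = "event",
) -> pd.DataFrame:
    """Minimum Bonferroni-corrected pairwise log-rank p value per k.

    For each k, subgroups are the silhouette-filtered consensus labels; all
    pairwise log-rank tests are run, corrected by the number of pairs
    tested, and the smallest corrected p is reported. Pairs where either
    subgroup has fewer than two events are skipped with a warning.
    """
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    rows = []
    for r in sorted(results, key=lambda x: x.k):
        kept, _ = silhouette_filter(r)
        labels = r.labels.loc[kept]
        groups = {
            lab: clin.loc[ids.index]
            for lab, ids in labels.groupby(labels)
        }
        pvals = []
        labs = sorted(groups)
        n_pairs = 0
        for i, la in enumerate(labs):
            for lb in labs[i + 1:]:
                ga, gb = groups[la], groups[lb]
                if ga[event_col].sum() < 2 or gb[event_col].sum() < 2:
                    warnings.warn(
                        f"k={r.k}: pair ({la},{lb}) skipped (<2 events in a subgroup)"
                    )
                    continue
                n_pairs += 1
                _, p = logrank(
                    ga[time_col], ga[event_col], gb[time_col], gb[event_col]
                )
                pvals.append(p)
        if not pvals:
            rows.append({"k": r.k, "min_corrected_p": np.nan, "n_pairs": 0})
            continue
        corrected = np.minimum(1.0, np.array(pvals) * n_pairs)
        rows.append(
            {"k": r.k, "min_corrected_p": float(corrected.min()), "n_pairs": n_pairs}
        )
    return pd.DataFrame(rows)
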