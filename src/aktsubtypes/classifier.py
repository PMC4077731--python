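"""Correlation-boundary nearest-centroid classification of new samples.

Each discovered subgroup is represented by the panel profiles of its member
samples plus a lower boundary: the minimum pairwise Pearson correlation
among members. A new sample qualifies for a subgroup when its average
correlation with the members exceeds that boundary, and is assigned to the
qualifying subgroup with the highest average correlation ("closest
cluster"); a sample clearing no boundary stays unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocessing import ExpressionMatrix

__all__ = ["SubtypeModel", "AssignmentResult", "fit_boundaries", "assign_sample", "assign_cohort"]


@dataclass(frozen=True)
class SubtypeModel:
    """Member panel profiles and lower correlation boundary per subgroup."""

    members: Mapping[object, pd.DataFrame]  # label -> genes x member samples
    boundaries: Mapping[object, float]
    panel_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        for lab, b in self.boundaries.items():
            if not -1.0 <= b <= 1.0:
                raise ValueError(f"boundary for {lab!r} outside [-1, 1]: {b}")
            if self.members[lab].shape[1] < 2:
                raise ValueError(f"cluster {lab!r} has fewer than 2 members")

    @property
    def labels(self) -> list:
        return sorted(self.members)


@dataclass(frozen=True)
class AssignmentResult:
    sample_id: str
    assigned: object | None  # None = unassigned
    avg_correlations: Mapping[object, float]
    qualifying: tuple

    def __post_init__(self) -> None:
        if self.assigned is not None and self.assigned not in self.qualifying:
            raise ValueError("assigned label must be among qualifying clusters")


def _pairwise_min_correlation(profiles: np.ndarray) -> float:
    """Minimum Pearson r over all sample pairs (columns)."""
    r = np.corrcoef(profiles.T)
    iu = np.triu_indices(r.shape[0], k=1)
    return float(r[iu].min())


def fit_boundaries(labels: pd.Series, panel_matrix: ExpressionMatrix) -> SubtypeModel:
    """Build a SubtypeModel from labeled (silhouette-filtered) samples.

    Boundary per cluster = min within-cluster pairwise Pearson correlation
    on the panel genes. Singleton clusters have no pairs and are dropped
    with a warning.
    """
    labels = labels.loc[labels.index.intersection(panel_matrix.sample_ids)]
    members: dict[object, pd.DataFrame] = {}
    boundaries: dict[object, float] = {}
    for lab in sorted(pd.unique(labels)):
        ids = labels.index[labels == lab]
        if len(ids) < 2:
            warnings.warn(f"cluster {lab!r} is a singleton and was dropped from the model")
            continue
        profiles = panel_matrix.data[list(ids)]
        members[lab] = profiles
        boundaries[lab] = _pairwise_min_correlation(profiles.to_numpy(dtype=float))
    if not members:
        raise ValueError("no cluster with >= 2 members; cannot fit boundaries")
    return SubtypeModel(
        members=members, boundaries=boundaries, panel_genes=tuple(panel_matrix.gene_ids)
    )


def assign_sample(
    x: pd.Series, model: SubtypeModel, min_shared_genes: int = 10
) -> AssignmentResult:
    """Assign one panel profile to a subgroup, or leave it unassigned.

    Genes absent from either side are dropped symmetrically (the classifier
    tolerates platforms missing a few panel probes). The sample qualifies
    for every cluster whose lower boundary its average member correlation
    strictly exceeds, and takes the qualifying cluster with the largest
    average correlation; exact ties break by cluster label order.
    """
    shared = [g for g in model.panel_genes if g in x.index]
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} shared panel genes (< {min_shared_genes})"
        )
    xv = x.loc[shared].to_numpy(dtype=float)
    avg: dict[object, float] = {}
    xc = xv - xv.mean()
    xnorm = np.linalg.norm(xc)
    if xnorm == 0:
        raise ValueError("constant profile: correlation undefined")
    for lab in model.labels:
        prof = model.members[lab].loc[shared].to_numpy(dtype=float)
        pc = prof - prof.mean(axis=0, keepdims=True)
        pnorm = np.linalg.norm(pc, axis=0)
        rs = (xc @ pc) / (xnorm * pnorm)
        avg[lab] = float(np.mean(rs))
    qualifying = tuple(lab for lab in model.labels if avg[lab] > model.boundaries[lab])
    assigned = None
    if qualifying:
        best = max(avg[lab] for lab in qualifying)
        assigned = next(lab for lab in qualifying if avg[lab] == best)
    name = str(x.name) if x.name is not None else "<unnamed>"
    return AssignmentResult(
        sample_id=name, assigned=assigned, avg_correlations=avg, qualifying=qualifying
    )


def assign_cohort(
    matrix: ExpressionMatrix,
    model: SubtypeModel,
    min_shared_genes: int = 10,
    min_members: int = 3,
) -> tuple[list[AssignmentResult], pd.DataFrame]:
    """Assign every cohort sample; summarize counts and flag tiny clusters.

    Clusters attracting fewer than ``min_members`` assigned samples are
    flagged for exclusion from downstream analysis (a cluster that barely
    maps onto a validation cohort is not characterized there).
    """
    results = [
        assign_sample(matrix.data[s], model, min_shared_genes=min_shared_genes)
        for s in matrix.sample_ids
    ]
    counts: dict[object, int] = {}
    for r in results:
        if r.assigned is not None:
            counts[r.assigned] = counts.get(r.assigned, 0) + 1
    rows = []
    for lab in model.labels:
        c = counts.get(lab, 0)
        rows.append({"cluster": lab, "n_assigned": c, "flagged": c < min_members})
    summary = pd.DataFrame(rows)
    summary.attrs["n_unassigned"] = sum(1 for r in results if r.assigned is None)
    return results, summary
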