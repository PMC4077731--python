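"""Expression-matrix preparation: median centering and classifier-panel selection.

The subtype discovery pipeline operates on a log2 expression matrix
(genes x samples) that has been median centered per gene, restricted to a
panel of pathway genes with high variability across tumors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GenePanel",
    "median_center",
    "select_panel",
    "subset_to_panel",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples log2 expression values.

    ``data`` is indexed by gene ID with sample IDs as columns. ``centered``
    records whether each gene row has been shifted to median zero.
    """

    data: pd.DataFrame
    centered: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        if np.isinf(self.data.to_numpy(dtype=float, na_value=np.nan)).any():
            raise ValueError("expression matrix contains infinite values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass(frozen=True)
class GenePanel:
    """Classifier gene panel with per-gene variability scores.

    ``scores`` is sorted non-increasing; ``source_list`` holds the candidate
    pathway genes the panel was drawn from.
    """

    gene_ids: tuple[str, ...]
    scores: tuple[float, ...]
    source_list: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("gene_ids and scores length mismatch")
        if any(b > a for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("variability scores must be sorted non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)


def median_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Shift every gene row to median zero.

    Idempotent; rows without at least one finite value are rejected.
    """
    vals = m.data.to_numpy(dtype=float)
    finite_counts = np.isfinite(vals).sum(axis=1)
    if (finite_counts < 1).any():
        bad = m.gene_ids[finite_counts < 1].tolist()
        raise ValueError(f"gene rows with no finite values: {bad[:5]}")
    medians = np.nanmedian(vals, axis=1, keepdims=True)
    centered = pd.DataFrame(vals - medians, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(centered, centered=True)


def _dispersion(vals: np.ndarray, statistic: Literal["sd", "mad"]) -> np.ndarray:
    if statistic == "sd":
        return np.nanstd(vals, axis=1, ddof=1)
    if statistic == "mad":
        med = np.nanmedian(vals, axis=1, keepdims=True)
        return np.nanmedian(np.abs(vals - med), axis=1)
    raise ValueError(f"unknown variability statistic: {statistic!r}")


def select_panel(
    m: ExpressionMatrix,
    candidates: Sequence[str],
    n_keep: int = 69,
    statistic: Literal["sd", "mad"] = "sd",
) -> GenePanel:
    """Keep the ``n_keep`` most variable candidate genes present in ``m``.

    Variability defaults to the sample standard deviation per gene row; the
    median absolute deviation is available as an alternative. Ties are broken
    lexicographically by gene ID so the selection is deterministic.
    """
    if not m.centered:
        raise ValueError("select_panel expects a median-centered matrix")
    candidates = list(dict.fromkeys(candidates))
    if not candidates:
        raise ValueError("candidate gene list is empty")
    present = [g for g in candidates if g in m.data.index]
    if n_keep > len(present):
        raise ValueError(
            f"n_keep={n_keep} exceeds {len(present)} candidate genes present in the matrix"
        )
    sub = m.data.loc[present]
    scores = pd.Series(_dispersion(sub.to_numpy(dtype=float), statistic), index=sub.index)
    # sort by descending score, ascending gene ID for ties
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    top = order[:n_keep]
    return GenePanel(
        gene_ids=tuple(top),
        scores=tuple(float(scores[g]) for g in top),
        source_list=tuple(candidates),
    )


def subset_to_panel(m: ExpressionMatrix, panel: GenePanel) -> ExpressionMatrix:
    """Restrict the matrix to panel genes, dropping panel genes it lacks.

    Mirrors cross-platform validation where a handful of panel probes are
    absent on the second platform: missing genes are dropped (never imputed)
    and logged.
    """
    present = [g for g in panel.gene_ids if g in m.data.index]
    missing = [g for g in panel.gene_ids if g not in m.data.index]
    if not present:
        raise ValueError("no panel genes present in the matrix")
    if missing:
        logger.warning(
            "%d of %d panel genes absent from matrix and dropped: %s",
            len(missing), len(panel), ", ".join(missing),
        )
    return ExpressionMatrix(m.data.loc[present], centered=m.centered)
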