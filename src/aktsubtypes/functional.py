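"""Single-sample GO enrichment and subgroup pathway-profile summaries.

Cohort-level enrichment of tumor expression is dominated by processes
common to all tumors, so enrichment is computed per sample: genes at least
two-fold above (or below) their cohort median are tested against each gene
set with the upper-tail hypergeometric test, Benjamini-Hochberg corrected
within the sample, and terms are then summarized by their prevalence
within each subgroup. Analyte (protein/phospho) z-score tables are
summarized per subgroup, including within-subgroup correlations between
named analyte pairs.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocessing import ExpressionMatrix

__all__ = [
    "per_sample_deg",
    "hypergeom_term_test",
    "enrich_sample",
    "enrich_cohort",
    "term_prevalence",
    "subgroup_profile",
]

#: log2 of the two-fold change threshold from the cohort median
_LOG2_TWOFOLD = 1.0


def per_sample_deg(m: ExpressionMatrix, sample: str) -> tuple[set[str], set[str]]:
    """Up- and down-regulated gene sets for one sample.

    A gene is "up" in the sample when its value is at least two-fold above
    the gene's cohort median (>= median + 1 on the log2 scale), "down" when
    at least two-fold below. Thresholds are inclusive.
    """
    if sample not in m.data.columns:
        raise KeyError(f"sample {sample!r} not in matrix")
    medians = m.data.median(axis=1)
    vals = m.data[sample]
    up = set(m.data.index[vals >= medians + _LOG2_TWOFOLD])
    down = set(m.data.index[vals <= medians - _LOG2_TWOFOLD])
    return up, down


def hypergeom_term_test(
    gene_list: set[str], term_genes: set[str], universe: set[str]
) -> float:
    """Upper-tail hypergeometric p value P[X >= overlap].

    N = |universe|, K = |term|, n = |gene list|; overlap counts genes in
    both list and term. An overlap of zero gives p = 1.
    """
    if not universe:
        raise ValueError("empty universe")
    if not term_genes <= universe:
        raise ValueError("term genes must be a subset of the universe")
    gene_list = gene_list & universe
    overlap = len(gene_list & term_genes)
    return float(stats.hypergeom.sf(overlap - 1, len(universe), len(term_genes), len(gene_list)))


def _build_universe(
    m: ExpressionMatrix,
    gene_sets: Mapping[str, Sequence[str]],
    universe: str = "annotated",
) -> set[str]:
    measured = set(m.data.index)
    if universe == "all":
        return measured
    if universe == "annotated":
        annotated = set().union(*(set(g) for g in gene_sets.values()))
        return measured & annotated
    raise ValueError(f"unknown universe policy {universe!r}")


def enrich_sample(
    m: ExpressionMatrix,
    sample: str,
    gene_sets: Mapping[str, Sequence[str]],
    q_threshold: float = 0.05,
    universe: str = "annotated",
) -> pd.DataFrame:
    """Hypergeometric enrichment of one sample's up/down gene lists.

    Up and down lists are tested separately against every term; BH
    correction is applied across the whole (term x direction) family
    within the sample. Returns a long-format frame with columns sample,
    term, direction, overlap, p, q, enriched.
    """
    uni = _build_universe(m, gene_sets, universe)
    up, down = per_sample_deg(m, sample)
    rows = []
    for direction, genes in (("up", up & uni), ("down", down & uni)):
        for term, tg in gene_sets.items():
            tg = set(tg) & uni
            if not tg:
                continue
            p = hypergeom_term_test(genes, tg, uni)
            rows.append(
                {
                    "sample": sample,
                    "term": term,
                    "direction": direction,
                    "overlap": len(genes & tg),
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(q=[], enriched=[])
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["enriched"] = out["q"] < q_threshold
    return out


def enrich_cohort(
    m: ExpressionMatrix,
    gene_sets: Mapping[str, Sequence[str]],
    q_threshold: float = 0.05,
    universe: str = "annotated",
) -> pd.DataFrame:
    """Per-sample enrichment for every sample in the matrix, concatenated."""
    frames = [
        enrich_sample(m, s, gene_sets, q_threshold=q_threshold, universe=universe)
        for s in m.sample_ids
    ]
    return pd.concat(frames, ignore_index=True)


def term_prevalence(
    enrichments: pd.DataFrame,
    labels: pd.Series,
    min_prevalence: float = 0.20,
    highlight_at: float = 0.40,
) -> pd.DataFrame:
    """Fraction of each subgroup's samples in which each term is enriched.

    A term counts for a sample when any direction is enriched. Rows are
    kept only at strictly greater than ``min_prevalence`` and flagged when
    prevalence reaches ``highlight_at``.
    """
    hits = enrichments[enrichments["enriched"]]
    rows = []
    for lab in sorted(pd.unique(labels)):
        ids = set(labels.index[labels == lab])
        n = len(ids)
        if n == 0:
            continue
        sub = hits[hits["sample"].isin(ids)]
        for term, grp in sub.groupby("term"):
            count = grp["sample"].nunique()
            prev = count / n
            if prev > min_prevalence:
                rows.append(
                    {
                        "subgroup": lab,
                        "term": term,
                        "n_enriched": count,
                        "n_samples": n,
                        "prevalence": prev,
                        "highlighted": prev >= highlight_at,
                    }
                )
    return pd.DataFrame(rows, columns=[
        "subgroup", "term", "n_enriched", "n_samples", "prevalence", "highlighted"
    ]).sort_values(["subgroup", "prevalence"], ascending=[True, False], ignore_index=True)


def subgroup_profile(
    analytes: pd.DataFrame,
    labels: pd.Series,
    pair: tuple[str, str] | None = None,
    min_group_size: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-subgroup mean analyte profile and optional analyte-pair correlation.

    ``analytes`` is analytes x samples (z-scores). When ``pair`` names two
    analytes, their Pearson correlation is computed within each subgroup;
    groups smaller than ``min_group_size`` have the correlation withheld.
    """
    common = labels.index.intersection(analytes.columns)
    labels = labels.loc[common]
    means = {
        lab: analytes[labels.index[labels == lab]].mean(axis=1)
        for lab in sorted(pd.unique(labels))
    }
    mean_table = pd.DataFrame(means)

    corr_table = None
    if pair is not None:
        a, b = pair
        rows = []
        for lab in sorted(pd.unique(labels)):
            ids = labels.index[labels == lab]
            if len(ids) < min_group_size:
                rows.append({"subgroup": lab, "n": len(ids), "r": np.nan})
                continue
            r = float(np.corrcoef(
                analytes.loc[a, ids].to_numpy(dtype=float),
                analytes.loc[b, ids].to_numpy(dtype=float),
            )[0, 1])
            rows.append({"subgroup": lab, "n": len(ids), "r": r})
        corr_table = pd.DataFrame(rows)
    return mean_table, corr_table
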