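"""One-vs-rest enrichment statistics for clinical and molecular features.

Continuous features are compared by a two-group one-way ANOVA F test,
categorical features by the likelihood-ratio (G) test, pairwise group
differences by Tukey's HSD, and small-count multinomial proportions by a
Monte-Carlo Pearson goodness-of-fit test with standardized residuals to
localize the deviating subgroups. Bonferroni correction is applied over an
explicitly supplied family size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentReport",
    "f_test_one_vs_rest",
    "lr_test_categorical",
    "tukey_hsd_pairwise",
    "mc_goodness_of_fit",
    "bonferroni",
]


@dataclass(frozen=True)
class EnrichmentReport:
    feature: str
    subgroup: object
    statistic: float
    p: float
    p_bonferroni: float
    direction: str
    detail: dict

    def __post_init__(self) -> None:
        if self.p_bonferroni + 1e-12 < self.p:
            raise ValueError("Bonferroni p cannot be below raw p")


def bonferroni(p: float, n_hypotheses: int) -> float:
    return float(min(1.0, p * n_hypotheses))


def f_test_one_vs_rest(
    values: pd.Series,
    labels: pd.Series,
    target: object,
    feature: str = "value",
    n_hypotheses: int = 1,
) -> EnrichmentReport:
    """Two-group one-way ANOVA F test of target subgroup vs the pooled rest."""
    values = values.loc[labels.index]
    a = values[labels == target].dropna().to_numpy(dtype=float)
    b = values[labels != target].dropna().to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples on each side")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        warnings.warn(f"{feature}: zero variance on both sides; p set to 1")
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.f_oneway(a, b)
    direction = "up" if a.mean() > b.mean() else "down"
    return EnrichmentReport(
        feature=feature,
        subgroup=target,
        statistic=float(stat),
        p=float(p),
        p_bonferroni=bonferroni(float(p), n_hypotheses),
        direction=direction,
        detail={"mean_in": float(a.mean()), "mean_rest": float(b.mean()),
                "n_in": len(a), "n_rest": len(b)},
    )


def g_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    """Likelihood-ratio statistic G = 2 * sum O * ln(O/E); 0*ln(0) = 0."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    mask = o > 0
    return float(2.0 * np.sum(o[mask] * np.log(o[mask] / e[mask])))


def lr_test_categorical(
    feature_values: pd.Series,
    labels: pd.Series,
    target: object,
    feature: str = "feature",
    n_hypotheses: int = 1,
) -> EnrichmentReport:
    """Likelihood-ratio (G) test of a categorical feature, target vs rest.

    Builds the 2 x c contingency table of (in target subgroup) x feature
    category; G is referred to a chi-square with c - 1 degrees of freedom.
    """
    feature_values = feature_values.loc[labels.index]
    in_group = (labels == target)
    table = pd.crosstab(in_group, feature_values)
    if (table.shape[0] < 2 or table.shape[1] < 2
            or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()):
        raise ValueError("contingency table has an empty margin (need 2 rows, >= 2 categories)")
    o = table.to_numpy(dtype=float)
    e = np.outer(o.sum(axis=1), o.sum(axis=0)) / o.sum()
    g = g_statistic(o, e)
    df = o.shape[1] - 1
    p = float(stats.chi2.sf(g, df))
    # direction: is the first non-reference category over-represented in-group?
    props_in = o[1] / o[1].sum()
    props_rest = o[0] / o[0].sum()
    direction = "up" if props_in[-1] >= props_rest[-1] else "down"
    return EnrichmentReport(
        feature=feature,
        subgroup=target,
        statistic=g,
        p=p,
        p_bonferroni=bonferroni(p, n_hypotheses),
        direction=direction,
        detail={"table": table, "df": df},
    )


def tukey_hsd_pairwise(values: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Tukey HSD pairwise mean differences with studentized-range p values.

    Singleton groups are dropped with a warning (the studentized range
    needs within-group replication).
    """
    values = values.loc[labels.index]
    groups, names = [], []
    for lab in sorted(pd.unique(labels)):
        g = values[labels == lab].dropna().to_numpy(dtype=float)
        if len(g) < 2:
            warnings.warn(f"group {lab!r} has < 2 samples and was dropped")
            continue
        groups.append(g)
        names.append(lab)
    if len(groups) < 2:
        raise ValueError("need at least two groups with >= 2 samples")
    res = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": float(groups[i].mean() - groups[j].mean()),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def mc_goodness_of_fit(
    observed: Sequence[int],
    null_proportions: Sequence[float],
    n_sim: int = 10_000,
    seed: int = 0,
) -> dict:
    """Monte-Carlo Pearson goodness-of-fit test for small multinomial counts.

    The Pearson chi-square statistic is referred to its exact multinomial
    null distribution by simulation; the p value uses the add-one estimator
    (1 + #{simulated >= observed}) / (n_sim + 1), which can never be zero.
    Standardized residuals (O - E) / sqrt(E (1 - p_i)) localize subgroups
    deviating from the null proportions; |residual| > 2 is flagged.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(null_proportions, dtype=float)
    if o.sum() < 1:
        raise ValueError("observed total must be >= 1")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("null proportions must sum to 1")
    n_total = int(round(o.sum()))
    e = n_total * p
    if (e == 0).any():
        raise ValueError("zero expected cell count")
    chi2_obs = float(np.sum((o - e) ** 2 / e))

    rng = np.random.default_rng(seed)
    sims = rng.multinomial(n_total, p, size=n_sim)
    chi2_sim = np.sum((sims - e) ** 2 / e, axis=1)
    p_mc = float((1 + np.sum(chi2_sim >= chi2_obs - 1e-12)) / (n_sim + 1))

    resid = (o - e) / np.sqrt(e * (1.0 - p))
    return {
        "statistic": chi2_obs,
        "p": p_mc,
        "residuals": resid,
        "flagged": np.abs(resid) > 2.0,
        "expected": e,
        "n_sim": n_sim,
    }
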