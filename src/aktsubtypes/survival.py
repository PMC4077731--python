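"""Survival comparisons between subgroups.

Kaplan-Meier estimation, pairwise and one-vs-rest log-rank tests, an
age-adjusted Cox proportional-hazards check, and the within-subgroup
treatment contrast that first truncates the cohort at a minimum age (so
that age and survival are decoupled in the remaining samples, leaving the
log-rank test interpretable without covariate adjustment).

Estimation and testing are delegated to lifelines; this module owns the
data marshaling and the reporting contracts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "KMEstimate",
    "km_curve",
    "logrank",
    "one_vs_rest_survival",
    "cox_age_adjust",
    "treatment_contrast",
]


@dataclass(frozen=True)
class KMEstimate:
    """Stepwise product-limit estimate with its median.

    ``median`` is the earliest time where the survival estimate falls to
    0.5 or below; ``None`` when the curve never reaches 0.5 (reported as
    undefined rather than substituting the last observed time).
    """

    survival: pd.Series  # indexed by time
    median: float | None
    n: int
    n_events: int


def km_curve(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimator with median survival."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no observations")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    surv = kmf.survival_function_["KM_estimate"]
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    if events.sum() == 0:
        warnings.warn("all observations censored; median survival undefined")
        median = None
    return KMEstimate(survival=surv, median=median, n=len(times), n_events=int(events.sum()))


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    Ties are handled with the standard hypergeometric variance. Each group
    must be non-empty and contribute at least one event overall.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def one_vs_rest_survival(
    labels: pd.Series,
    clinical: pd.DataFrame,
    time_col: str = "os_years",
    event_col: str = "event",
) -> pd.DataFrame:
    """Per-subgroup log-rank of the subgroup against the pooled rest.

    Returns one row per subgroup: group median, rest median, chi-square
    statistic and p. Subgroups with no events are skipped with a warning.
    """
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    labels = labels.loc[labels.index.intersection(clin.index)]
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError("need at least two subgroups")
    rows = []
    for lab in uniq:
        in_ids = labels.index[labels == lab]
        out_ids = labels.index[labels != lab]
        gin, gout = clin.loc[in_ids], clin.loc[out_ids]
        if gin[event_col].sum() == 0 or gout[event_col].sum() == 0:
            warnings.warn(f"subgroup {lab!r} skipped: no events on one side")
            continue
        stat, p = logrank(gin[time_col], gin[event_col], gout[time_col], gout[event_col])
        rows.append(
            {
                "subgroup": lab,
                "n": len(gin),
                "median": km_curve(gin[time_col], gin[event_col]).median,
                "rest_median": km_curve(gout[time_col], gout[event_col]).median,
                "statistic": stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def cox_age_adjust(
    labels: pd.Series,
    clinical: pd.DataFrame,
    target: object,
    time_col: str = "os_years",
    event_col: str = "event",
    age_col: str = "age",
) -> pd.DataFrame:
    """Cox PH fit of a subgroup indicator adjusted for age.

    Returns the coefficient table (hazard ratio, SE, z, p per covariate);
    convergence problems propagate as errors rather than being silenced.
    """
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    labels = labels.loc[labels.index.intersection(clin.index)]
    df = pd.DataFrame(
        {
            "time": clin.loc[labels.index, time_col].astype(float),
            "event": clin.loc[labels.index, event_col].astype(int),
            "in_group": (labels == target).astype(int).to_numpy(),
            "age": clin.loc[labels.index, age_col].astype(float),
        }
    )
    if df["in_group"].sum() == 0:
        raise ValueError(f"no samples labeled {target!r}")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    out = cph.summary[["coef", "exp(coef)", "se(coef)", "z", "p"]].copy()
    out.columns = ["coef", "hazard_ratio", "se", "z", "p"]
    return out


def treatment_contrast(
    clinical: pd.DataFrame,
    labels: pd.Series,
    subgroup: object,
    treatment_col: str = "alkylator",
    age_floor: float = 45.0,
    time_col: str = "os_years",
    event_col: str = "event",
    age_col: str = "age",
) -> dict:
    """Treated-vs-untreated log-rank within one subgroup, after an age floor.

    Samples younger than ``age_floor`` are removed first; within the
    remaining subgroup members, treated and untreated arms are compared by
    log-rank and both arm medians are reported.
    """
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    ids = labels.index[labels == subgroup].intersection(clin.index)
    sub = clin.loc[ids]
    sub = sub[sub[age_col] >= age_floor]
    if len(sub) == 0:
        raise ValueError(f"no subgroup {subgroup!r} samples at or above age {age_floor}")
    treated = sub[sub[treatment_col] == 1]
    untreated = sub[sub[treatment_col] == 0]
    if len(treated) == 0 or len(untreated) == 0:
        raise ValueError(
            f"empty treatment arm after age filter (treated={len(treated)}, "
            f"untreated={len(untreated)})"
        )
    stat, p = logrank(
        treated[time_col], treated[event_col], untreated[time_col], untreated[event_col]
    )
    return {
        "subgroup": subgroup,
        "age_floor": age_floor,
        "n_treated": len(treated),
        "n_untreated": len(untreated),
        "median_treated": km_curve(treated[time_col], treated[event_col]).median,
        "median_untreated": km_curve(untreated[time_col], untreated[event_col]).median,
        "statistic": stat,
        "p": p,
    }
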