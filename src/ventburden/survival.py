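"""Survival models: average-power quartiles, Kaplan-Meier with log-rank,
univariate and backward-stepwise Cox proportional-hazards models, and
descriptive cohort tables.

All survival analyses are on 28-day mortality: survivors are censored at
day 28. Tied event times use the Efron approximation (lifelines default).
The stepwise procedure is backward elimination from the univariate
p < 0.2 candidate set, dropping the largest-p variable until all retained
variables have p < 0.05; ties break toward the lexicographically first
name so the output is invariant to covariate column order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "assign_quartiles",
    "KMResult",
    "km_logrank",
    "cox_univariate",
    "cox_stepwise",
    "descriptive_tables",
    "UNIVARIATE_ENTRY_P",
    "STEPWISE_STAY_P",
]

UNIVARIATE_ENTRY_P = 0.2
STEPWISE_STAY_P = 0.05
HORIZON_DAYS = 28.0


def assign_quartiles(summaries: pd.DataFrame) -> pd.DataFrame:
    """Quartile membership by whole-course average power.

    Cutoffs are the 25th/50th/75th percentiles of ``avg_mp``; membership is
    by stable rank order so group sizes differ by at most one even with
    heavy ties. Returns patient_id, avg_mp, quartile (1-4) with the cutoffs
    in ``DataFrame.attrs["cutoffs"]``.
    """
    if len(summaries) < 4:
        raise ValueError("need at least 4 patients to form quartiles")
    df = summaries[["patient_id", "avg_mp"]].copy()
    order = np.lexsort((df["patient_id"].to_numpy(), df["avg_mp"].to_numpy()))
    rank = np.empty(len(df), dtype=np.int64)
    rank[order] = np.arange(len(df))
    df["quartile"] = (rank * 4) // len(df) + 1
    df.attrs["cutoffs"] = tuple(
        float(v) for v in np.percentile(df["avg_mp"], [25, 50, 75])
    )
    return df


@dataclass
class KMResult:
    """Product-limit curves per group plus the k-sample log-rank test."""

    survival_functions: dict
    statistic: float
    p_value: float


def km_logrank(
    data: pd.DataFrame,
    group_col: str = "quartile",
    time_col: str = "survival_time_days",
    event_col: str = "event",
    horizon: float = HORIZON_DAYS,
) -> KMResult:
    """Kaplan-Meier curves per group and the log-rank test across groups.

    Times are clipped at ``horizon`` with events beyond it censored.
    """
    df = data[[group_col, time_col, event_col]].copy()
    if (df[time_col] < 0).any():
        raise ValueError("negative survival times")
    over = df[time_col] > horizon
    df.loc[over, event_col] = 0
    df[time_col] = df[time_col].clip(upper=horizon)

    curves = {}
    for g, sub in df.groupby(group_col, sort=True):
        if len(sub) == 0:
            raise ValueError(f"group {g!r} has no patients")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col], label=str(g))
        curves[g] = kmf.survival_function_
    if df[group_col].nunique() < 2:
        return KMResult(curves, 0.0, 1.0)
    res = multivariate_logrank_test(df[time_col], df[group_col], df[event_col])
    return KMResult(curves, float(res.test_statistic), float(res.p_value))


def _fit_cox(
    data: pd.DataFrame, covariates: list[str], time_col: str, event_col: str
) -> pd.DataFrame:
    cph = CoxPHFitter()
    cph.fit(
        data[[time_col, event_col, *covariates]],
        duration_col=time_col,
        event_col=event_col,
    )
    s = cph.summary
    return pd.DataFrame(
        {
            "variable": s.index,
            "hr": s["exp(coef)"].to_numpy(),
            "ci_lower": s["exp(coef) lower 95%"].to_numpy(),
            "ci_upper": s["exp(coef) upper 95%"].to_numpy(),
            "p": s["p"].to_numpy(),
        }
    ).reset_index(drop=True)


def cox_univariate(
    data: pd.DataFrame,
    covariates: list[str],
    time_col: str = "survival_time_days",
    event_col: str = "event",
) -> pd.DataFrame:
    """One proportional-hazards fit per covariate on 28-day survival."""
    if data[covariates].isna().any().any():
        raise ValueError("covariate matrix contains missing values")
    frames = []
    for cov in covariates:
        df = _fit_cox(data, [cov], time_col, event_col)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["stage"] = "univariate"
    return out


def cox_stepwise(
    univariate: pd.DataFrame,
    data: pd.DataFrame,
    time_col: str = "survival_time_days",
    event_col: str = "event",
    entry_p: float = UNIVARIATE_ENTRY_P,
    stay_p: float = STEPWISE_STAY_P,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Backward stepwise multivariate Cox model.

    Candidates are covariates with univariate p < ``entry_p``. The
    largest-p variable is removed (ties to the lexicographically first
    name) and the model refitted until every remaining variable has
    p < ``stay_p``. Returns (final model with retained flags for all
    candidates, full-candidate sensitivity model).
    """
    candidates = sorted(
        univariate.loc[univariate["p"] < entry_p, "variable"].tolist()
    )
    if not candidates:
        raise ValueError("no candidate covariates with univariate p < entry_p")

    full = _fit_cox(data, candidates, time_col, event_col)
    full["stage"] = "multivariate-full"

    kept = list(candidates)
    fitted = full.copy()
    while kept:
        worst = fitted.sort_values(
            ["p", "variable"], ascending=[False, True], kind="mergesort"
        ).iloc[0]
        if worst["p"] < stay_p:
            break
        kept.remove(worst["variable"])
        if not kept:
            fitted = fitted.iloc[0:0]
            break
        fitted = _fit_cox(data, kept, time_col, event_col)

    final = fitted.copy()
    final["stage"] = "multivariate"
    final["retained"] = True
    dropped = pd.DataFrame(
        {
            "variable": [c for c in candidates if c not in kept],
            "hr": np.nan, "ci_lower": np.nan, "ci_upper": np.nan, "p": np.nan,
            "stage": "multivariate", "retained": False,
        }
    )
    final = pd.concat([final, dropped], ignore_index=True)
    final = final.sort_values("variable", kind="mergesort").reset_index(drop=True)
    return final, full


_STRATA_LABELS = ("> 300", "> 200 to <= 300", "> 100 to <= 200", "<= 100")


def pf_stratum(pf_ratio: pd.Series) -> pd.Series:
    """First-day P/F stratum label (mmHg) for each patient."""
    bins = [-np.inf, 100.0, 200.0, 300.0, np.inf]
    labels = list(reversed(_STRATA_LABELS))
    return pd.cut(pf_ratio, bins=bins, labels=labels).astype(str)


def _median_iqr(x: pd.Series) -> str:
    q1, med, q3 = np.percentile(x.dropna(), [25, 50, 75])
    return f"{med:g} ({q1:g}, {q3:g})"


def _count_pct(x: pd.Series) -> str:
    n = int(x.sum())
    return f"{n} ({100.0 * n / len(x):.1f}%)"


def descriptive_tables(
    patients: pd.DataFrame,
    continuous: list[str],
    categorical: list[str],
) -> pd.DataFrame:
    """Median (IQR) / count (%) summaries, overall and per P/F stratum.

    Continuous variables are compared across strata with the Kruskal-Wallis
    rank test, categorical ones with the chi-square test.
    """
    strata = pf_stratum(patients["pf_ratio"])
    groups = [patients[strata == lab] for lab in _STRATA_LABELS]
    rows = []
    for var in continuous:
        row = {"variable": var, "overall": _median_iqr(patients[var])}
        for lab, g in zip(_STRATA_LABELS, groups):
            row[lab] = _median_iqr(g[var]) if len(g) else ""
        samples = [g[var].dropna() for g in groups if len(g) > 0]
        row["p"] = (
            float(stats.kruskal(*samples).pvalue) if len(samples) > 1 else np.nan
        )
        rows.append(row)
    for var in categorical:
        x = patients[var].astype(int)
        row = {"variable": var, "overall": _count_pct(x)}
        for lab, g in zip(_STRATA_LABELS, groups):
            row[lab] = _count_pct(g[var].astype(int)) if len(g) else ""
        tab = pd.crosstab(strata, x)
        row["p"] = (
            float(stats.chi2_contingency(tab).pvalue)
            if tab.shape[0] > 1 and tab.shape[1] > 1
            else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
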