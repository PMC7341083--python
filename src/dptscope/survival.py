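"""Survival association of immune-infiltrate density.

Patients are dichotomized on a covariate (sample median by default,
ties to "low"), compared by Kaplan-Meier curves with a two-group
log-rank test, and the covariate effect is estimated by a univariate
Cox proportional-hazards model (Efron tie handling — follow-up in
months produces heavy ties).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["dichotomize", "km_logrank", "cox_univariate"]


def dichotomize(
    records: pd.DataFrame, covariate: str, rule: str | float = "median"
) -> pd.DataFrame:
    """Assign a high/low ``group`` column by a covariate cutoff.

    ``rule="median"`` uses the sample median (values equal to the
    cutoff go to "low"); a numeric rule is used as a fixed threshold.
    """
    if covariate not in records.columns:
        raise KeyError(f"covariate '{covariate}' absent")
    v = records[covariate].to_numpy(dtype=float)
    cutoff = float(np.median(v)) if rule == "median" else float(rule)
    out = records.copy()
    out["group"] = np.where(v > cutoff, "high", "low")
    if (out["group"] == out["group"].iloc[0]).all():
        warnings.warn("degenerate dichotomization: all patients in one group", stacklevel=2)
    out.attrs["cutoff"] = cutoff
    return out


def km_logrank(records: pd.DataFrame, group_col: str = "group") -> dict:
    """Kaplan-Meier curves per group plus the two-group log-rank test.

    Returns ``{"curves": {group: DataFrame}, "chi2": float, "p": float}``;
    the statistic is the usual sum of (O - E)^2 / V referred to
    chi-square with 1 df.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    if records.empty:
        raise ValueError("no survival records")
    groups = list(pd.unique(records[group_col]))
    curves = {}
    for g in groups:
        sub = records[records[group_col] == g]
        km = KaplanMeierFitter()
        km.fit(sub["time_months"], event_observed=sub["event"].astype(bool), label=str(g))
        sf = km.survival_function_
        curves[g] = sf.rename(columns={sf.columns[0]: "survival"})
    if len(groups) != 2:
        raise ValueError("log-rank here is the two-group statistic")
    a = records[records[group_col] == groups[0]]
    b = records[records[group_col] == groups[1]]
    res = logrank_test(
        a["time_months"], b["time_months"],
        event_observed_A=a["event"].astype(bool),
        event_observed_B=b["event"].astype(bool),
    )
    return {"curves": curves, "chi2": float(res.test_statistic), "p": float(res.p_value)}


def cox_univariate(
    records: pd.DataFrame, covariate: str = "group"
) -> dict:
    """Univariate Cox proportional-hazards fit.

    A ``group`` covariate is coded high = 1 / low = 0. Returns hazard
    ratio, 95% CI, Wald p, beta and SE; non-convergence (e.g. complete
    separation / monotone likelihood) is flagged rather than raised:
    ``{"converged": False, ...}``.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = records[["time_months", "event"]].copy()
    df["event"] = df["event"].astype(bool)
    if covariate == "group":
        df["x"] = (records["group"].astype(str) == "high").astype(float)
    else:
        df["x"] = records[covariate].astype(float)
    if len(df) < 3 or df["x"].nunique() < 2:
        return {"converged": False, "reason": "non-estimable: too few records or constant covariate"}
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time_months", event_col="event")
    except (ConvergenceError, ValueError) as exc:
        return {"converged": False, "reason": str(exc)}
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    return {
        "converged": True,
        "hr": float(np.exp(beta)),
        "ci_low": float(np.exp(beta - 1.96 * se)),
        "ci_high": float(np.exp(beta + 1.96 * se)),
        "p": float(cph.summary.loc["x", "p"]),
        "beta": beta,
        "se": se,
    }
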