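"""Survival and regression statistics for the combined proteomic test.

Kaplan-Meier curves and a log-rank test compare patients with a positive
versus a negative combined bile/urine proteomic test; multivariate logistic
regression relates one-year mortality to the test result and the usual
demographic/laboratory covariates, reported as Wald odds ratios with 95%
confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .errors import ValidationError

__all__ = [
    "SurvivalRecord",
    "km_estimate",
    "logrank_test",
    "fit_logistic_multivariate",
    "odds_ratio_ci",
    "survival_report",
    "censor_at",
]

Z_95 = 1.959964  # two-sided 95% normal quantile


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time (days, > 0), death event flag, stratum."""

    sample_id: str
    time: float
    event: bool
    stratum: str

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValidationError(f"time must be > 0, got {self.time}")


def _to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        missing = {"time", "event"} - set(df.columns)
        if missing:
            raise ValidationError(f"records lack column(s): {sorted(missing)}")
    else:
        df = pd.DataFrame([{
            "sample_id": r.sample_id, "time": r.time,
            "event": r.event, "stratum": r.stratum,
        } for r in records])
    if df.empty:
        raise ValidationError("need at least one record")
    if not (df["time"] > 0).all():
        raise ValidationError("all times must be > 0")
    return df


def km_estimate(records) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Accepts SurvivalRecords or a DataFrame with ``time`` and ``event``
    columns. Returns a step function as a DataFrame (time, survival)
    starting at (0, 1); with no censoring this equals the empirical survival
    function.
    """
    df = _to_frame(records)
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"].astype(bool))
    sf = kmf.survival_function_
    out = sf.reset_index()
    out.columns = ["time", "survival"]
    return out


def logrank_test(records, strata: Sequence[str] | None = None) -> tuple[float, float]:
    """Log-rank comparison of exactly two strata; returns (chi-square, p).

    ``strata`` optionally names the two stratum labels to compare; by default
    the records' own (exactly two) stratum values are used.
    """
    df = _to_frame(records)
    if "stratum" not in df.columns:
        raise ValidationError("records lack a 'stratum' column")
    levels = list(strata) if strata is not None else sorted(df["stratum"].unique())
    if len(levels) != 2:
        raise ValidationError(f"log-rank requires exactly 2 strata, got {levels}")
    a = df[df["stratum"] == levels[0]]
    b = df[df["stratum"] == levels[1]]
    if a.empty or b.empty:
        raise ValidationError("both strata must be non-empty")
    if int(df["event"].sum()) < 1:
        raise ValidationError("log-rank requires at least one event")
    res = _ll_logrank(a["time"], b["time"],
                      event_observed_A=a["event"].astype(bool),
                      event_observed_B=b["event"].astype(bool))
    return float(res.test_statistic), float(res.p_value)


def odds_ratio_ci(coefficient: float, se: float, level: float = 0.95
                  ) -> tuple[float, float, float]:
    """Wald odds ratio with confidence interval: exp(coef -/+ z * se)."""
    if se < 0:
        raise ValidationError("standard error must be >= 0")
    z = Z_95 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2))
    return (float(np.exp(coefficient)),
            float(np.exp(coefficient - z * se)),
            float(np.exp(coefficient + z * se)))


@dataclass
class LogisticFit:
    """Multivariate logistic regression results with Wald odds ratios."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    converged: bool
    separation: bool = False
    _sm_result: object = field(default=None, repr=False)

    def table(self, round_to: int = 2) -> pd.DataFrame:
        """Report mirroring the usual clinical presentation: coefficient,
        SE, p, OR and 95% CI (OR columns rounded to ``round_to`` decimals)."""
        rows = []
        for name in self.params.index:
            orr, lo, hi = odds_ratio_ci(self.params[name], self.bse[name])
            rows.append({
                "variable": name,
                "coefficient": self.params[name], "se": self.bse[name],
                "p": self.pvalues[name],
                "odds_ratio": round(orr, round_to),
                "ci_lower": round(lo, round_to), "ci_upper": round(hi, round_to),
            })
        return pd.DataFrame(rows).set_index("variable")

    def summary(self):
        return self._sm_result.summary() if self._sm_result is not None else self.table()


def fit_logistic_multivariate(
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary outcome.

    Newton/IRLS with convergence tolerance 1e-8; Wald standard errors from
    the inverse observed information. Requires >= 10 records and both
    outcome classes; perfect separation is flagged rather than fatal.
    """
    if len(data) < 10:
        raise ValidationError("need >= 10 records")
    y = data[outcome].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome must contain both classes")
    cov = data[list(covariates)].astype(float)
    # constant covariates are collinear with the intercept: report them with
    # coefficient 0 instead of letting the information matrix go singular
    constant = [c for c in cov.columns if cov[c].nunique() == 1]
    X = sm.add_constant(cov.drop(columns=constant), has_constant="add")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(method="newton", tol=1e-8, maxiter=100, disp=0)
        except Exception:
            res = None
            separation = True
        if res is not None and any("separat" in str(w.message).lower() for w in caught):
            separation = True
    order = ["const"] + list(covariates)

    def with_constants(series: pd.Series, fill: float) -> pd.Series:
        full = series.reindex(order)
        for c in constant:
            full[c] = fill
        return full

    if res is None:
        try:
            ridge = sm.Logit(y, X).fit_regularized(alpha=1e-3, L1_wt=0.0, disp=0)
            params = pd.Series(np.asarray(ridge.params, float), index=X.columns)
        except Exception:
            params = pd.Series(0.0, index=X.columns)
        nan = pd.Series(np.nan, index=X.columns)
        warnings.warn("perfect separation; ridge fallback used", stacklevel=2)
        return LogisticFit(with_constants(params, 0.0), with_constants(nan, np.nan),
                           with_constants(nan, np.nan),
                           converged=False, separation=True)
    return LogisticFit(
        params=with_constants(
            pd.Series(np.asarray(res.params, float), index=X.columns), 0.0),
        bse=with_constants(
            pd.Series(np.asarray(res.bse, float), index=X.columns), np.nan),
        pvalues=with_constants(
            pd.Series(np.asarray(res.pvalues, float), index=X.columns), np.nan),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation=separation, _sm_result=res,
    )


def censor_at(df: pd.DataFrame, horizon: float = 365.0) -> pd.DataFrame:
    """Administratively censor follow-up at the horizon (death within the
    horizon keeps its event flag; later events become censored)."""
    out = df.copy()
    late = out["time"] > horizon
    out.loc[late, "event"] = 0
    out.loc[late, "time"] = horizon
    out["event"] = out["event"].astype(int)
    return out


def survival_report(records, strata: Sequence[str] | None = None) -> dict:
    """Stratified survival summary for the proteomic test.

    Per stratum: n, number of deaths, death rate in percent (1 decimal, as
    printed in clinical reports) and the KM curve. Plus the log-rank
    chi-square and p, and the 2x2 death odds ratio (positive vs negative
    stratum) with Wald 95% CI from the table counts.
    """
    df = _to_frame(records)
    levels = list(strata) if strata is not None else sorted(df["stratum"].unique())
    per_stratum = {}
    for lev in levels:
        sub = df[df["stratum"] == lev]
        deaths = int(sub["event"].sum())
        n = int(len(sub))
        per_stratum[lev] = {
            "n": n, "deaths": deaths,
            "death_rate_pct": round(100.0 * deaths / n, 1) if n else float("nan"),
            "km": km_estimate(sub),
        }
    chi2, p = logrank_test(df, strata=levels)
    result = {"strata": per_stratum, "logrank_chi2": chi2, "logrank_p": p}
    if len(levels) == 2:
        d1, n1 = per_stratum[levels[1]]["deaths"], per_stratum[levels[1]]["n"]
        d0, n0 = per_stratum[levels[0]]["deaths"], per_stratum[levels[0]]["n"]
        # Wald OR on the 2x2 table (second stratum vs first)
        a, b, c, d = d1, n1 - d1, d0, n0 - d0
        if min(a, b, c, d) > 0:
            logor = np.log(a * d / (b * c))
            se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            result["odds_ratio"] = odds_ratio_ci(logor, se)
    return result


def plot_km(records, strata: Sequence[str] | None = None, ax=None):
    """Kaplan-Meier curves per stratum (thin wrapper over lifelines)."""
    import matplotlib.pyplot as plt

    df = _to_frame(records)
    levels = list(strata) if strata is not None else sorted(df["stratum"].unique())
    if ax is None:
        _, ax = plt.subplots()
    for lev in levels:
        sub = df[df["stratum"] == lev]
        kmf = KaplanMeierFitter(label=str(lev))
        kmf.fit(sub["time"], event_observed=sub["event"].astype(bool))
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("days since endoscopy")
    ax.set_ylabel("overall survival")
    return ax
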