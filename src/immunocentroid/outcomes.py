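"""Clinical endpoint computation and association statistics.

Response rates follow the standard oncology definitions (ORR = CR+PR over
evaluable patients; disease control adds SD; clinical benefit adds only SD
lasting >= 6 months, supplied as a flag). Survival uses the Kaplan-Meier
product-limit estimator, the two-group log-rank test and Cox proportional
hazards with Efron tie handling (all via lifelines); association tests are
the Fisher exact test (two-sided probability-mass rule, sample odds
ratio), the tie-corrected Kruskal-Wallis test, and multivariable logistic
regression with separation detection (statsmodels).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .containers import ClinicalTable


@dataclass
class ResponseRates:
    """Cohort response rates over evaluable (non-NA best response) samples.

    Percentages are the proportions rounded to the nearest whole percent
    (half away from zero), the display convention of clinical tables.
    """

    n_evaluable: int
    orr: float
    disease_control: float
    clinical_benefit_rate: float

    def __post_init__(self) -> None:
        for name in ("orr", "disease_control", "clinical_benefit_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.orr > self.disease_control:
            raise ValueError("ORR cannot exceed the disease-control rate")

    @staticmethod
    def _pct(x: float) -> int:
        return int(math.floor(100.0 * x + 0.5))  # half away from zero (x >= 0)

    @property
    def orr_percent(self) -> int:
        return self._pct(self.orr)

    @property
    def disease_control_percent(self) -> int:
        return self._pct(self.disease_control)

    @property
    def clinical_benefit_percent(self) -> int:
        return self._pct(self.clinical_benefit_rate)


def response_rates(clin: ClinicalTable) -> ResponseRates:
    """ORR, disease-control and clinical-benefit rates from a clinical table."""
    df = clin.data
    evaluable = df[df["best_response"] != "NA"]
    n = len(evaluable)
    if n == 0:
        raise ValueError("no evaluable samples (all best_response are NA)")
    resp = evaluable["best_response"]
    n_cr_pr = int(resp.isin(["CR", "PR"]).sum())
    n_dc = int(resp.isin(["CR", "PR", "SD"]).sum())
    n_benefit = int(evaluable["clinical_benefit"].fillna(False).astype(bool).sum())
    return ResponseRates(
        n_evaluable=n,
        orr=n_cr_pr / n,
        disease_control=n_dc / n,
        clinical_benefit_rate=n_benefit / n,
    )


@dataclass
class SurvivalCurve:
    """Kaplan-Meier step function with at-risk counts.

    ``median`` is the earliest time with survival <= 0.5, or None when not
    reached.
    """

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray
    median: float | None

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step-function query."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival_prob,
                "at_risk": self.at_risk,
            }
        )


def kaplan_meier(times: np.ndarray, events: np.ndarray) -> SurvivalCurve:
    """Product-limit survival estimate from right-censored data."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table.iloc[1:] if 0.0 not in times else kmf.event_table
    # keep only times where the curve can change (events) plus censor steps
    sf = kmf.survival_function_["KM_estimate"]
    grid = sf.index.to_numpy(dtype=float)
    probs = sf.to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    median = kmf.median_survival_time_
    median = None if np.isinf(median) else float(median)
    # drop the leading t=0 anchor row lifelines inserts unless data start at 0
    return SurvivalCurve(grid, probs, at_risk, median)


def logrank(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError(f"logrank requires exactly 2 groups, got {len(levels)}")
    a = group == levels[0]
    res = logrank_test(times[a], times[~a], event_observed_A=events[a],
                       event_observed_B=events[~a])
    return float(res.test_statistic), float(res.p_value)


def cox_ph(times, events, covariates: pd.DataFrame) -> pd.DataFrame:
    """Cox proportional hazards (Efron ties) on right-censored endpoints.

    Returns a per-covariate table with log HR, HR, 95% CI and Wald p.
    Raises on constant covariates (no information) and wraps lifelines
    convergence failures in a ValueError.
    """
    covariates = pd.DataFrame(covariates).reset_index(drop=True)
    if not np.all(np.isfinite(covariates.to_numpy(dtype=float))):
        raise ValueError("covariates must be finite")
    constant = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if constant:
        raise ValueError(f"covariates with a single value carry no information: {constant}")
    events = np.asarray(events, dtype=bool)
    if events.sum() == 0:
        raise ValueError("Cox model requires at least one event")
    df = covariates.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = events.astype(int)
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="_time", event_col="_event")
    except Exception as err:  # convergence / separation
        raise ValueError(f"Cox model failed to converge: {err}") from err
    summ = fitter.summary
    return pd.DataFrame(
        {
            "log_hr": summ["coef"],
            "hr": np.exp(summ["coef"]),
            "ci_low": np.exp(summ["coef"] - 1.96 * summ["se(coef)"]),
            "ci_high": np.exp(summ["coef"] + 1.96 * summ["se(coef)"]),
            "wald_p": summ["p"],
        }
    )


def fisher_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    p sums the probabilities of all tables (fixed margins) no more likely
    than the observed one; the odds ratio is the sample odds ratio
    (ad/bc, inf when bc = 0).
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("fisher_2x2 requires a 2x2 table")
    if np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ValueError("table entries must be non-negative integers")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("fisher_2x2 rejects tables with an all-zero margin")
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(odds), float(p)


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H test across >= 2 groups.

    All-identical values give H = 0, p = 1 (the degenerate-tie convention:
    a fully tied sample carries no rank information).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def adjusted_logistic(
    response,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Multivariable logistic regression of a binary response.

    Returns a per-term table (including the intercept) with estimate, SE
    and Wald p. Complete or quasi-complete separation is detected and
    reported by flagging non-finite / exploding estimates in a
    ``separation`` column instead of failing.
    """
    y = np.asarray(response, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both response classes must be present")
    X = sm.add_constant(pd.DataFrame(covariates).reset_index(drop=True), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params, bse, pvals = fit.params, fit.bse, fit.pvalues
        except Exception:
            # fall back to a ridge-free irls that may not converge; report raw
            fit = sm.Logit(y, X).fit(disp=0, maxiter=35, method="bfgs")
            params, bse, pvals = fit.params, fit.bse, fit.pvalues
    table = pd.DataFrame({"estimate": params, "se": bse, "wald_p": pvals})
    # heuristic separation flag: exploding coefficient or SE
    table["separation"] = (~np.isfinite(table["estimate"])
                           | ~np.isfinite(table["se"])
                           | (table["estimate"].abs() > 15)
                           | (table["se"] > 100))
    if table["separation"].any():
        warnings.warn(
            "possible separation: non-finite or extreme logistic estimates for "
            f"{list(table.index[table['separation']])}"
        )
    return table
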