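"""Statistical layer: variance explained, stepwise models, group contrasts.

Given a subjects × metrics cohort table, this module quantifies how much of
overall physical activity (mean counts/15 s, LMVPA and MVPA min/day) is
captured by step-based metrics:

* simple OLS of each outcome on each single step-based predictor (r²);
* forward stepwise selection: start from the best single predictor, keep
  adding the candidate with the largest r² gain while its partial F-test is
  significant (α = .05); after each addition, any included predictor whose
  variance inflation factor exceeds 7 is dropped permanently (highest VIF
  first).  Time at zero cadence never enters the predictor pool, since it
  represents inactivity rather than activity;
* two-sample t tests (pooled variance by default, Welch optional)
  contrasting children who do and do not meet the >=60 min/day MVPA
  guideline;
* inversion of the fitted MVPA regression line to the predictor value at
  which the line reaches the guideline dose, with a delta-method CI.

Model fitting is delegated to statsmodels/scipy; the selection procedure
and the threshold inversion are implemented here.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .io_epoch import ConfigError, StepmetricsError
from .metrics import BAND_COLUMNS


class DegeneratePredictorError(StepmetricsError):
    """Predictor (or outcome) with zero variance."""


class NonInvertibleError(StepmetricsError):
    """Regression slope nonpositive or indistinguishable from zero."""


class InsufficientGroupError(StepmetricsError):
    """A comparison group has fewer than two members."""


OUTCOMES = ["mean_counts15", "lmvpa_min", "mvpa_min"]

#: Canonical predictor order: steps/day, cadence bands ascending, then peak
#: cadences by descending window length.  Ties in r² gain are broken by this
#: order; TZC is deliberately absent.
STEP_PREDICTORS = ["steps_per_day", *BAND_COLUMNS, "peak60", "peak30", "peak1"]


@dataclasses.dataclass
class RegressionResult:
    outcome: str
    predictors: list[str]
    r_squared: float
    coefficients: dict[str, float]  # includes "intercept"
    n: int


@dataclasses.dataclass
class StepwiseResult:
    outcome: str
    selected: list[str]
    increments: list[dict]          # per-event log: add/drop, predictor, r² after
    r_squared: float
    vif: dict[str, float]
    dropped: list[str]
    alpha: float
    vif_limit: float


@dataclasses.dataclass
class GroupComparison:
    metric: str
    mean_meets: float
    sd_meets: float
    n_meets: int
    mean_not: float
    sd_not: float
    n_not: int
    t: float
    p: float


@dataclasses.dataclass
class ThresholdResult:
    predictor: str
    threshold: float
    ci_low: float
    ci_high: float
    intercept: float
    slope: float
    r_squared: float
    n: int


def _fit(cohort: pd.DataFrame, outcome: str, predictors: list[str]):
    y = cohort[outcome].to_numpy(float)
    X = sm.add_constant(cohort[list(predictors)].to_numpy(float))
    return sm.OLS(y, X).fit()


def variance_explained(cohort: pd.DataFrame, outcome: str,
                       predictor: str) -> RegressionResult:
    """Simple linear regression of *outcome* on a single *predictor*."""
    if len(cohort) < 3:
        raise ConfigError("need n >= 3 for regression")
    x = cohort[predictor].to_numpy(float)
    if np.ptp(x) == 0:
        raise DegeneratePredictorError(f"{predictor} has zero variance")
    res = _fit(cohort, outcome, [predictor])
    return RegressionResult(
        outcome=outcome,
        predictors=[predictor],
        r_squared=float(res.rsquared),
        coefficients={"intercept": float(res.params[0]),
                      predictor: float(res.params[1])},
        n=int(res.nobs),
    )


def single_r2_table(cohort: pd.DataFrame,
                    outcomes: list[str] = OUTCOMES,
                    predictors: list[str] = STEP_PREDICTORS) -> pd.DataFrame:
    """Tidy table of simple-regression r² for every outcome × predictor."""
    rows = [
        {"outcome": o, "predictor": p,
         "r_squared": variance_explained(cohort, o, p).r_squared}
        for o in outcomes for p in predictors
    ]
    return pd.DataFrame(rows)


def stepwise_select(cohort: pd.DataFrame, outcome: str,
                    pool: list[str] | None = None,
                    alpha: float = 0.05,
                    vif_limit: float = 7.0) -> StepwiseResult:
    """Forward stepwise selection with per-step VIF screening.

    At each step the candidate with the largest r² gain is added if its
    partial F-test has p < *alpha* (for a single added regressor this is
    the squared-t test of its coefficient).  After each addition, included
    predictors with VIF > *vif_limit* are dropped permanently, highest VIF
    first; dropped predictors become ineligible.  Selection stops when no
    candidate qualifies.
    """
    pool = list(STEP_PREDICTORS if pool is None else pool)
    if not pool:
        raise ConfigError("empty predictor pool")
    if "tzc_min" in pool:
        raise ConfigError("TZC represents inactivity and must not be a predictor")

    selected: list[str] = []
    dropped: list[str] = []
    log: list[dict] = []
    current_r2 = 0.0

    while True:
        candidates = [p for p in pool if p not in selected and p not in dropped]
        if not candidates:
            break
        best, best_r2, best_p = None, -np.inf, 1.0
        for cand in candidates:  # pool order breaks exact ties
            res = _fit(cohort, outcome, selected + [cand])
            if res.rsquared > best_r2 + 1e-12:
                best, best_r2 = cand, float(res.rsquared)
                best_p = float(res.pvalues[len(selected) + 1])
        if best is None or best_p >= alpha:
            break
        selected.append(best)
        current_r2 = best_r2
        log.append({"action": "add", "predictor": best,
                    "r_squared": current_r2, "p": best_p})
        # VIF screening of the current model
        while len(selected) >= 2:
            exog = sm.add_constant(cohort[selected].to_numpy(float))
            with np.errstate(divide="ignore"):  # exact collinearity -> inf VIF
                vifs = np.array([variance_inflation_factor(exog, j + 1)
                                 for j in range(len(selected))])
            if (vifs <= vif_limit).all():
                break
            worst = int(np.argmax(vifs))
            victim = selected.pop(worst)
            dropped.append(victim)
            current_r2 = (float(_fit(cohort, outcome, selected).rsquared)
                          if selected else 0.0)
            log.append({"action": "drop", "predictor": victim,
                        "r_squared": current_r2, "vif": float(vifs[worst])})

    final_vif: dict[str, float] = {}
    if len(selected) >= 2:
        exog = sm.add_constant(cohort[selected].to_numpy(float))
        with np.errstate(divide="ignore"):
            final_vif = {p: float(variance_inflation_factor(exog, j + 1))
                         for j, p in enumerate(selected)}
    elif len(selected) == 1:
        final_vif = {selected[0]: 1.0}
    return StepwiseResult(outcome, selected, log, current_r2, final_vif,
                          dropped, alpha, vif_limit)


def compare_groups(cohort: pd.DataFrame, metric: str,
                   group_col: str = "meets_guideline",
                   welch: bool = False) -> GroupComparison:
    """Two-sample t test of *metric* between guideline groups.

    Pooled-variance Student's t by default; set ``welch=True`` for the
    unequal-variance variant.
    """
    meets = cohort.loc[cohort[group_col].astype(bool), metric].to_numpy(float)
    not_meets = cohort.loc[~cohort[group_col].astype(bool), metric].to_numpy(float)
    if len(meets) < 2 or len(not_meets) < 2:
        raise InsufficientGroupError(
            f"{metric}: group sizes {len(meets)}/{len(not_meets)} too small")
    t, p = sps.ttest_ind(meets, not_meets, equal_var=not welch)
    return GroupComparison(
        metric=metric,
        mean_meets=float(meets.mean()), sd_meets=float(meets.std(ddof=1)),
        n_meets=len(meets),
        mean_not=float(not_meets.mean()), sd_not=float(not_meets.std(ddof=1)),
        n_not=len(not_meets),
        t=float(t), p=float(p),
    )


def group_comparison_table(cohort: pd.DataFrame,
                           metrics: list[str] | None = None,
                           welch: bool = False) -> pd.DataFrame:
    if metrics is None:
        metrics = ["tzc_min", *BAND_COLUMNS, "peak60", "peak30", "peak1"]
    return pd.DataFrame([dataclasses.asdict(compare_groups(cohort, m, welch=welch))
                         for m in metrics])


def guideline_threshold(cohort: pd.DataFrame, predictor: str,
                        mvpa_target: float = 60.0,
                        outcome: str = "mvpa_min",
                        alpha: float = 0.05) -> ThresholdResult:
    """Predictor value at which the fitted MVPA line reaches the guideline.

    Fits ``outcome = a + b * predictor`` and returns ``(target - a) / b``
    with a delta-method 95% CI from the coefficient covariance.  Raises if
    the slope is nonpositive or not significantly different from zero.
    """
    res = _fit(cohort, outcome, [predictor])
    a, b = float(res.params[0]), float(res.params[1])
    if b <= 0 or float(res.pvalues[1]) >= alpha:
        raise NonInvertibleError(
            f"{predictor}: slope {b:.4g} (p={float(res.pvalues[1]):.3g}) "
            "not invertible")
    theta = (mvpa_target - a) / b
    grad = np.array([-1.0 / b, -theta / b])
    var = float(grad @ res.cov_params() @ grad)
    half = sps.norm.ppf(0.975) * math.sqrt(max(var, 0.0))
    return ThresholdResult(
        predictor=predictor, threshold=float(theta),
        ci_low=float(theta - half), ci_high=float(theta + half),
        intercept=a, slope=b, r_squared=float(res.rsquared), n=int(res.nobs),
    )


def thresholds_table(cohort: pd.DataFrame,
                     predictors: list[str] = STEP_PREDICTORS,
                     mvpa_target: float = 60.0) -> pd.DataFrame:
    """Guideline thresholds for every invertible step-based predictor."""
    rows = []
    for p in predictors:
        try:
            rows.append(dataclasses.asdict(
                guideline_threshold(cohort, p, mvpa_target)))
        except NonInvertibleError:
            continue
    return pd.DataFrame(rows)
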