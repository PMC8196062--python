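"""Ontogenetic trends: kinematics vs age, and orientation success vs age.

Two trend analyses run over the per-larva results table:

* ordinary least squares of mean swimming speed (cm/s) and mean absolute
  turning angle (deg) on age (days post-hatch), with 95% confidence bands
  for the mean prediction from the t-distribution;
* logistic regression of the binary outcome "oriented" on age, fitted by
  iteratively reweighted least squares, with a likelihood-ratio chi-square
  (df = 1) against the intercept-only model. A non-significant slope means
  the proportion of larvae that orient does not change through development.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["LarvaResult", "TrendFit", "fit_linear_trend", "fit_orientation_logistic",
           "trend_curve_frame"]

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100


@dataclass
class LarvaResult:
    """One row per deployment: kinematics, frame analysis, classification."""

    deployment_id: str
    age_dph: int
    mean_speed_cm_s: float
    mean_turning_deg: float
    classification: str
    bearing_cardinal_deg: float
    rho: float
    p_cardinal: float

    def __post_init__(self) -> None:
        if self.age_dph < 0:
            raise ValueError(f"{self.deployment_id}: negative age")
        if self.classification not in ("non_oriented", "device_biased", "oriented"):
            raise ValueError(f"{self.deployment_id}: bad classification {self.classification!r}")


@dataclass
class TrendFit:
    """A fitted trend of one response on age.

    For the linear trends ``test_stat`` is the slope t-statistic with
    ``df = n - 2``; for the logistic trend it is the likelihood-ratio
    chi-square with ``df = 1``. ``ci95_band(ages)`` returns (point, lower,
    upper) arrays for the mean response at the given ages.
    """

    response: str
    slope: float
    intercept: float
    test_stat: float
    df: int
    p: float
    n: int
    ci95_band: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray, np.ndarray]]
    slope_se: float = float("nan")
    reliable: bool = True
    deviance_trace: list = field(default_factory=list)

    def slope_ci95(self) -> tuple[float, float]:
        """95% confidence interval for the slope (t for OLS, Wald for logistic)."""
        crit = stats.t.ppf(0.975, self.df) if self.response != "oriented" else stats.norm.ppf(0.975)
        return self.slope - crit * self.slope_se, self.slope + crit * self.slope_se


def fit_linear_trend(results, response: str) -> TrendFit:
    """OLS of a kinematic response ("speed" or "turning") on age."""
    cols = {"speed": "mean_speed_cm_s", "turning": "mean_turning_deg"}
    if response not in cols:
        raise ValueError(f"response must be one of {sorted(cols)}, got {response!r}")
    age = np.array([lr.age_dph for lr in results], dtype=float)
    y = np.array([getattr(lr, cols[response]) for lr in results], dtype=float)
    ok = np.isfinite(y)
    age, y = age[ok], y[ok]
    if age.size < 3:
        raise ValueError("linear trend needs at least 3 larvae")
    if np.ptp(age) == 0:
        raise ValueError("all ages identical; slope unidentifiable")
    model = sm.OLS(y, sm.add_constant(age)).fit()
    intercept, slope = model.params

    def band(ages):
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        pred = model.get_prediction(sm.add_constant(ages, has_constant="add"))
        frame = pred.summary_frame(alpha=0.05)
        return (
            frame["mean"].to_numpy(),
            frame["mean_ci_lower"].to_numpy(),
            frame["mean_ci_upper"].to_numpy(),
        )

    return TrendFit(
        response=response,
        slope=float(slope),
        intercept=float(intercept),
        test_stat=float(model.tvalues[1]),
        df=int(model.df_resid),
        p=float(model.pvalues[1]),
        n=int(age.size),
        ci95_band=band,
        slope_se=float(model.bse[1]),
    )


def _logistic_deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return -2.0 * float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _irls_logistic(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, list[float], bool]:
    """Fit logit(P(y=1)) = X beta by IRLS; returns (beta, deviance trace, converged)."""
    beta = np.zeros(x.shape[1])
    trace: list[float] = []
    converged = False
    for _ in range(IRLS_MAX_ITER):
        eta = x @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1 - p), 1e-10, None)
        z = eta + (y - p) / w
        xtw = x.T * w
        beta_new = np.linalg.solve(xtw @ x, xtw @ z)
        trace.append(_logistic_deviance(y, 1.0 / (1.0 + np.exp(-(x @ beta_new)))))
        if np.max(np.abs(beta_new - beta)) < IRLS_TOL:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    return beta, trace, converged


def fit_orientation_logistic(results) -> TrendFit:
    """Logistic regression of orientation success on age with an LR test.

    Outcome 1 = classified oriented, 0 = non-oriented or device-biased. With
    complete (or quasi-complete) separation the slope diverges and the
    statistic is flagged unreliable rather than reported as trustworthy.
    """
    age = np.array([lr.age_dph for lr in results], dtype=float)
    y = np.array([1.0 if lr.classification == "oriented" else 0.0 for lr in results])
    if y.min() == y.max():
        raise ValueError("logistic fit needs both outcome classes present")
    x = np.column_stack([np.ones_like(age), age])
    beta, trace, converged = _irls_logistic(x, y)
    p_hat = 1.0 / (1.0 + np.exp(-(x @ beta)))
    dev = _logistic_deviance(y, p_hat)
    # intercept-only deviance has the closed form of the binomial null
    pbar = float(np.mean(y))
    dev_null = _logistic_deviance(y, np.full_like(y, pbar))
    lr_chi2 = max(0.0, dev_null - dev)
    p_value = float(stats.chi2.sf(lr_chi2, df=1))
    separated = bool(np.all((p_hat > 1 - 1e-6) == (y == 1))) and np.any(p_hat > 1 - 1e-6)
    reliable = converged and not separated and abs(beta[1]) < 1e3
    if not reliable:
        log.warning(
            "logistic fit unreliable (converged=%s, separation=%s, slope=%.3g)",
            converged, separated, beta[1],
        )

    cov = None
    if reliable:
        w = p_hat * (1 - p_hat)
        cov = np.linalg.inv((x.T * w) @ x)

    def band(ages):
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        xa = np.column_stack([np.ones_like(ages), ages])
        eta = xa @ beta
        point = 1.0 / (1.0 + np.exp(-eta))
        if cov is None:
            return point, np.full_like(point, np.nan), np.full_like(point, np.nan)
        se = np.sqrt(np.einsum("ij,jk,ik->i", xa, cov, xa))
        zc = stats.norm.ppf(0.975)
        lo = 1.0 / (1.0 + np.exp(-(eta - zc * se)))
        hi = 1.0 / (1.0 + np.exp(-(eta + zc * se)))
        return point, lo, hi

    return TrendFit(
        response="oriented",
        slope=float(beta[1]),
        intercept=float(beta[0]),
        test_stat=float(lr_chi2),
        df=1,
        p=p_value,
        n=int(y.size),
        ci95_band=band,
        slope_se=float(np.sqrt(cov[1, 1])) if cov is not None else float("nan"),
        reliable=reliable,
        deviance_trace=trace,
    )


def trend_curve_frame(fit: TrendFit, ages) -> pd.DataFrame:
    """Fitted curve with its 95% band on an age grid, ready for CSV export."""
    ages = np.asarray(ages, dtype=float)
    point, lo, hi = fit.ci95_band(ages)
    return pd.DataFrame(
        {"response": fit.response, "age_dph": ages, "fit": point, "ci_lower": lo, "ci_upper": hi}
    )
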