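"""Single-compound concentration-response modelling.

Acute mortality data from microwell bioassays are modelled with a
two-parameter logit-log curve,

    logit F(c) = alpha + beta * log10(c),

where ``F(c)`` is the expected mortality fraction at concentration ``c``
(mg L^-1).  The module fits the curve either by binomial maximum likelihood
(logistic GLM) or by ordinary least squares on empirical-logit-transformed
proportions, and derives lethal concentrations LCx with delta-method
standard errors and symmetric 95% confidence intervals on the arithmetic
concentration scale.

Controls (concentration 0) are excluded from fitting and no background
mortality correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from .exceptions import (
    DegenerateResponseError,
    InsufficientDesignError,
    InvalidConcentrationError,
    NonMonotoneError,
)

__all__ = [
    "MortalityRecord",
    "LogitCurve",
    "LCxEstimate",
    "DoseResponseFit",
    "fit_dose_response",
    "predict_mortality",
    "lc_estimate",
    "curve_from_lcs",
    "records_to_frame",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class MortalityRecord:
    """Mortality count in one well (or pooled replicate) of an acute test.

    ``concentration`` is in mg L^-1; 0 is reserved for controls, which are
    excluded from curve fitting.
    """

    compound: str
    concentration: float
    n_exposed: int
    n_dead: int
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise InvalidConcentrationError(
                f"concentration must be >= 0, got {self.concentration}"
            )
        if not 0 <= self.n_dead <= self.n_exposed:
            raise ValueError(
                f"need 0 <= n_dead <= n_exposed, got {self.n_dead}/{self.n_exposed}"
            )


@dataclass(frozen=True)
class LogitCurve:
    """Two-parameter logit-log concentration-response curve.

    ``alpha`` is the intercept and ``beta`` the slope per decade of
    concentration; ``beta > 0`` for a toxicant (mortality increases with
    concentration).
    """

    alpha: float
    beta: float

    @property
    def lc50(self) -> float:
        """Concentration at 50% effect, ``10**(-alpha/beta)``."""
        return float(10.0 ** (-self.alpha / self.beta))

    def predict(self, concentration) -> np.ndarray | float:
        """Predicted mortality fraction at positive concentration(s)."""
        return predict_mortality(self, concentration)


@dataclass(frozen=True)
class LCxEstimate:
    """Lethal concentration at effect level ``x`` percent, with uncertainty.

    ``se`` and ``ci95`` are on the arithmetic concentration scale (mg L^-1);
    the interval is the symmetric delta-method Wald interval.
    """

    x: float
    value: float
    se: float
    ci95: tuple[float, float]
    r_squared: float | None = None


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted curve with parameter covariance and logit-scale diagnostics."""

    curve: LogitCurve
    covariance: np.ndarray  # 2x2, order (alpha, beta)
    r_squared: float
    method: str
    n_obs: int
    converged: bool = True

    def lc(self, x: float) -> LCxEstimate:
        est = lc_estimate(self.curve, self.covariance, x)
        return LCxEstimate(est.x, est.value, est.se, est.ci95, self.r_squared)


def records_to_frame(records: Iterable[MortalityRecord]) -> pd.DataFrame:
    """Tabulate mortality records (one row per record)."""
    return pd.DataFrame(
        [
            {
                "compound": r.compound,
                "conc_mg_L": r.concentration,
                "n_exposed": r.n_exposed,
                "n_dead": r.n_dead,
                "replicate": r.replicate_id,
            }
            for r in records
        ]
    )


def _empirical_logit(dead: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Boundary-safe logit of observed proportions.

    Interior proportions are transformed directly; boundary rows (0% or
    100% mortality) use the adjusted proportion (k + 0.5) / (n + 1), for
    which the logit is finite.
    """
    p = dead / n
    boundary = (dead == 0) | (dead == n)
    p = np.where(boundary, (dead + 0.5) / (n + 1.0), p)
    return logit(p)


def fit_dose_response(
    records: Iterable[MortalityRecord] | pd.DataFrame,
    method: str = "binomial_glm",
) -> DoseResponseFit:
    """Fit a logit-log curve to single-compound mortality data.

    Parameters
    ----------
    records
        Mortality records or a frame with columns
        ``conc_mg_L, n_exposed, n_dead``.  Controls (concentration 0) are
        dropped before fitting.
    method
        ``"binomial_glm"`` (default) maximizes the binomial likelihood of
        the well-level counts; ``"empirical_logit_ols"`` regresses
        empirical-logit proportions on log10 concentration by ordinary
        least squares.

    Returns
    -------
    DoseResponseFit
        Curve, 2x2 parameter covariance (alpha, beta), and the R^2 of the
        logit-scale fit computed against empirical logits.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = records_to_frame(records)
    df = df[df["conc_mg_L"] > 0]
    if df["conc_mg_L"].nunique() < 3:
        raise InsufficientDesignError(
            "insufficient design: need >= 3 distinct positive concentrations"
        )
    dead = df["n_dead"].to_numpy(float)
    n = df["n_exposed"].to_numpy(float)
    if np.all(dead == 0) or np.all(dead == n):
        raise DegenerateResponseError(
            "degenerate response: all-alive or all-dead at every concentration"
        )
    logc = np.log10(df["conc_mg_L"].to_numpy(float))
    exog = sm.add_constant(logc)

    if method == "binomial_glm":
        model = sm.GLM(
            np.column_stack([dead, n - dead]), exog, family=sm.families.Binomial()
        )
        res = model.fit()
        alpha, beta = (float(v) for v in res.params)
        cov = np.asarray(res.cov_params())
        converged = bool(res.converged)
    elif method == "empirical_logit_ols":
        y = _empirical_logit(dead, n)
        res = sm.OLS(y, exog).fit()
        alpha, beta = (float(v) for v in res.params)
        cov = np.asarray(res.cov_params())
        converged = True
    else:
        raise ValueError(f"unknown method {method!r}")

    # logit-scale goodness of fit against empirical logits
    y_emp = _empirical_logit(dead, n)
    y_hat = alpha + beta * logc
    sst = float(np.sum((y_emp - y_emp.mean()) ** 2))
    ssr = float(np.sum((y_emp - y_hat) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else float("nan")

    return DoseResponseFit(
        curve=LogitCurve(alpha, beta),
        covariance=cov,
        r_squared=r2,
        method=method,
        n_obs=len(df),
        converged=converged,
    )


def predict_mortality(curve: LogitCurve, concentration) -> np.ndarray | float:
    """Expected mortality fraction at a positive concentration.

    Vectorized over ``concentration``; every element must be > 0.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c <= 0):
        raise InvalidConcentrationError("invalid concentration: must be > 0")
    out = expit(curve.alpha + curve.beta * np.log10(c))
    return float(out) if np.isscalar(concentration) or c.ndim == 0 else out


def lc_estimate(curve: LogitCurve, covariance, x: float) -> LCxEstimate:
    """Lethal concentration at effect level ``x`` percent with delta-method SE.

    The point estimate is ``10**((logit(x/100) - alpha) / beta)``; its
    standard error propagates the (alpha, beta) covariance through the
    gradient of that mapping, and the 95% CI is ``value +/- 1.96 * SE`` on
    the arithmetic scale.
    """
    if not 0 < x < 100:
        raise ValueError(f"effect level must be in (0, 100), got {x}")
    if curve.beta <= 0:
        raise NonMonotoneError("non-monotone curve: beta must be > 0")
    cov = np.asarray(covariance, dtype=float)
    if cov.shape != (2, 2):
        raise ValueError("covariance must be 2x2 in (alpha, beta) order")
    target = float(logit(x / 100.0))
    value = 10.0 ** ((target - curve.alpha) / curve.beta)
    ln10 = np.log(10.0)
    grad = np.array(
        [
            -value * ln10 / curve.beta,
            -value * ln10 * (target - curve.alpha) / curve.beta**2,
        ]
    )
    var = float(grad @ cov @ grad)
    se = float(np.sqrt(max(var, 0.0)))
    return LCxEstimate(
        x=float(x),
        value=float(value),
        se=se,
        ci95=(float(value - _Z95 * se), float(value + _Z95 * se)),
    )


def curve_from_lcs(
    lc_a: Sequence[float], lc_b: Sequence[float]
) -> LogitCurve:
    """Reconstruct the unique logit-log curve through two (effect %, LC) points.

    Given ``(x_a, c_a)`` and ``(x_b, c_b)`` with distinct effect levels and
    distinct concentrations, solves

        beta  = (logit(x_b/100) - logit(x_a/100)) / (log10 c_b - log10 c_a)
        alpha = logit(x_a/100) - beta * log10 c_a

    The ordering must be consistent with a monotone increasing curve
    (higher effect at higher concentration).
    """
    (xa, ca), (xb, cb) = lc_a, lc_b
    if ca <= 0 or cb <= 0:
        raise InvalidConcentrationError("LC concentrations must be > 0")
    if xa == xb or ca == cb:
        raise NonMonotoneError("underdetermined: need distinct effect levels and concentrations")
    if (xb - xa) * (cb - ca) < 0:
        raise NonMonotoneError("non-monotone input: higher effect must pair with higher concentration")
    la, lb = float(logit(xa / 100.0)), float(logit(xb / 100.0))
    beta = (lb - la) / (np.log10(cb) - np.log10(ca))
    alpha = la - beta * np.log10(ca)
    return LogitCurve(float(alpha), float(beta))
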