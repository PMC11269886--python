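"""Regression engines and relative-prey-mass statistics.

Two single-covariate models answer the size questions.  A binomial GLM with
a logit link tests whether prey mass predicts ingestion success: the outcome
is 1 for a swallowed bird and 0 for a slimed one, the covariate is the
bird's mass at banding.  A Gaussian linear model tests, among successful
ingestions, whether predator mass predicts prey mass.  Both report Wald
tests (z against the standard normal for the GLM, t against Student-t with
n-2 degrees of freedom for the linear model), two-sided.

Relative prey mass (RPM) is prey mass divided by predator mass, the standard
measure of meal size in snake feeding ecology; a double meal contributes a
single RPM with the prey masses summed.

The GLM is fit by iteratively reweighted least squares (IRLS), the canonical
Newton scheme for the Bernoulli log-likelihood:

    w_i = p_i (1 - p_i),   z_i = eta_i + (y_i - p_i) / w_i,

then a weighted least-squares step on the working response z.  Standard
errors come from the inverse Fisher information at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_records import Outcome, PredationEvent

_IRLS_TOL = 1e-8
_IRLS_MAX_ITER = 50


class SeparationError(ValueError):
    """The Bernoulli likelihood has no finite maximizer (one outcome class)."""


class DegenerateDesignError(ValueError):
    """The design matrix is rank-deficient (constant covariate)."""


@dataclass(frozen=True)
class GlmFit:
    """A fitted logit-link binomial GLM with intercept and one slope."""

    coefficients: tuple[float, float]  # (intercept, slope)
    standard_errors: tuple[float, float]
    z_values: tuple[float, float]
    p_values: tuple[float, float]
    converged: bool
    n_iterations: int
    log_likelihood: float
    n_obs: int


@dataclass(frozen=True)
class OlsFit:
    """A fitted simple linear regression."""

    intercept: float
    slope: float
    slope_se: float
    t_value: float
    p_value: float
    df_resid: int
    r_squared: float


def _bernoulli_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    # log(1 + e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    outcomes: Sequence[int], covariate: Sequence[float]
) -> GlmFit:
    """Maximum-likelihood logistic regression of a binary outcome on one covariate.

    Parameters
    ----------
    outcomes
        0/1 outcomes (1 = ingested, 0 = slimed under the standard coding).
    covariate
        Continuous covariate, same length, n >= 3.

    Returns
    -------
    GlmFit
        Converged fit, or ``converged=False`` with the last iterate when the
        coefficient change never drops below 1e-8 within 50 iterations
        (quasi-separation); no exception is raised in that case.

    Raises
    ------
    SeparationError
        If only one outcome class is present: the MLE diverges.
    ValueError
        On length mismatch or n < 3.
    """
    y = np.asarray(outcomes, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape:
        raise ValueError("outcomes and covariate must have equal length")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not ((y == 0) | (y == 1)).all():
        raise ValueError("outcomes must be 0/1")
    pbar = y.mean()
    if pbar == 0.0 or pbar == 1.0:
        raise SeparationError("all outcomes identical: likelihood has no maximum")

    X = np.column_stack([np.ones(n), x])
    beta = np.array([math.log(pbar / (1.0 - pbar)), 0.0])
    converged = False
    it = 0
    for it in range(1, _IRLS_MAX_ITER + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        w = np.maximum(w, 1e-12)  # guard against exact 0/1 fitted values
        z = eta + (y - p) / w
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < _IRLS_TOL:
            converged = True
            break

    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(p * (1.0 - p), 1e-12)
    fisher = X.T @ (X * w[:, None])
    cov = np.linalg.inv(fisher)
    se = np.sqrt(np.diag(cov))
    zvals = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(zvals))
    return GlmFit(
        coefficients=(float(beta[0]), float(beta[1])),
        standard_errors=(float(se[0]), float(se[1])),
        z_values=(float(zvals[0]), float(zvals[1])),
        p_values=(float(pvals[0]), float(pvals[1])),
        converged=converged,
        n_iterations=it,
        log_likelihood=_bernoulli_loglik(beta, X, y),
        n_obs=n,
    )


def fit_ols(x: Sequence[float], y: Sequence[float]) -> OlsFit:
    """Simple least-squares regression of y on x with a residual-based slope SE.

    Raises
    ------
    DegenerateDesignError
        If x is constant.
    ValueError
        If n < 3 (no residual degrees of freedom for the t test).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0.0:
        raise DegenerateDesignError("degenerate design: x is constant")
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    df = n - 2
    sigma2 = float(resid @ resid) / df
    slope_se = math.sqrt(sigma2 / sxx)
    if slope_se > 0:
        t = slope / slope_se
        p = 2.0 * stats.t.sf(abs(t), df)
    else:  # perfect fit
        t = math.inf if slope != 0 else 0.0
        p = 0.0 if slope != 0 else 1.0
    syy = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / syy if syy > 0 else 1.0
    return OlsFit(
        intercept=intercept,
        slope=float(slope),
        slope_se=slope_se,
        t_value=float(t),
        p_value=float(p),
        df_resid=df,
        r_squared=r2,
    )


def wald_test(fit: GlmFit | OlsFit, which: int = 1) -> tuple[float, float]:
    """Two-sided Wald test on one coefficient of a converged fit.

    For a GLM the statistic is referred to the standard normal; for the
    linear model, to Student-t with the residual degrees of freedom.

    Raises
    ------
    ValueError
        If the fit did not converge (its standard errors are meaningless).
    """
    if isinstance(fit, GlmFit):
        if not fit.converged:
            raise ValueError("cannot run a Wald test on an unconverged fit")
        z = fit.z_values[which]
        return z, float(2.0 * stats.norm.sf(abs(z)))
    if which != 1:
        raise ValueError("only the slope is tested for an OLS fit")
    t = fit.t_value
    return t, float(2.0 * stats.t.sf(abs(t), fit.df_resid))


@dataclass(frozen=True)
class RpmSummary:
    """Summary of relative prey mass over successful ingestion events."""

    values: tuple[float, ...]
    mean: float
    se: float
    min: float
    max: float
    n: int

    @property
    def single_event(self) -> bool:
        """SE is zero by convention when only one event is summarized."""
        return self.n == 1


def compute_rpm(event: PredationEvent) -> float:
    """Relative prey mass of one successful ingestion: prey mass / predator mass.

    A double meal uses the summed prey mass.  Undefined for failed attempts
    (no predator was ever captured) and when predator mass is missing.
    """
    if event.outcome is not Outcome.INGESTED:
        raise ValueError("RPM is undefined for a failed ingestion attempt")
    if event.predator_mass_g is None:
        raise ValueError("predator mass is missing")
    return event.prey_mass_g / event.predator_mass_g


def rpm_summary(
    events: Sequence[PredationEvent], exclude_multi_prey: bool = False
) -> RpmSummary:
    """Mean, SE, range of RPM across successful events.

    ``exclude_multi_prey`` drops double meals (used for the prey-vs-predator
    scatter, where a two-bird meal is not a single prey item).
    """
    eligible = [
        e
        for e in events
        if e.outcome is Outcome.INGESTED
        and e.predator_mass_g is not None
        and not (exclude_multi_prey and len(e.bird_ids) > 1)
    ]
    if not eligible:
        raise ValueError("no eligible events for an RPM summary")
    vals = np.array([compute_rpm(e) for e in eligible])
    n = vals.size
    se = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return RpmSummary(
        values=tuple(float(v) for v in vals),
        mean=float(vals.mean()),
        se=se,
        min=float(vals.min()),
        max=float(vals.max()),
        n=int(n),
    )


__all__ = [
    "DegenerateDesignError",
    "GlmFit",
    "OlsFit",
    "RpmSummary",
    "SeparationError",
    "compute_rpm",
    "fit_logistic",
    "fit_ols",
    "rpm_summary",
    "wald_test",
]
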