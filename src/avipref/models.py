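"""Negative-binomial GLM model sets for feeding-bird density.

Each model set relates one response (migratory, year-round, or total
feeding-bird density per km) to a single street-tree predictor through a
log link, ``mu = exp(b0 + b1 x [+ b2 x^2])``, with negative-binomial
variance ``mu + mu^2 / theta``.  Nine models per set: eight predictors plus
the intercept-only model, ranked by AIC.

The responses are per-km densities and therefore not integers.  The NB
log-likelihood is evaluated through its continuous extension (gamma
functions in place of factorials), which is how standard GLM software
behaves when handed a non-integer response; ``integer_mode=True`` rounds
the response first for a strict count likelihood.

theta is profiled: for a fixed dispersion the mean model is fitted by
IRLS (statsmodels), and the outer 1-D likelihood in log(alpha), with
``alpha = 1/theta``, is maximized numerically to tolerance 1e-8.
Coefficients are reported exponentiated (a coefficient < 1 is a negative
relationship), with Wald z-test p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

log = logging.getLogger(__name__)

__all__ = [
    "ModelFitResult",
    "ModelSet",
    "DispersionReport",
    "fit_nb_glm",
    "fit_poisson_glm",
    "overdispersion_check",
    "rank_models",
    "fit_model_set",
    "DEFAULT_PREDICTORS",
]

#: The eight street-tree predictors of the standard model set.
DEFAULT_PREDICTORS = [
    "richness_per_km",
    "shannon",
    "tree_density",
    "native_tree_density",
    "nonnative_tree_density",
    "basal_area",
    "native_basal_area",
    "nonnative_basal_area",
]

TERM_NAMES = ("intercept", "linear", "quadratic")


@dataclass
class ModelFitResult:
    """One fitted GLM (negative binomial or Poisson)."""

    response: str
    predictor: str
    quadratic: bool
    family: str
    coef: np.ndarray  # link (log) scale
    beta_exp: np.ndarray  # exponentiated
    se: np.ndarray
    wald_p: np.ndarray
    theta: float
    llf: float
    aic: float
    deviance: float
    pearson_chi2: float
    df_resid: int
    dispersion_ratio: float
    converged: bool
    n: int
    delta_aic: float = np.nan
    fitted_mu: np.ndarray = field(default=None, repr=False)
    y: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        terms = TERM_NAMES[: len(self.coef)]
        return {
            "response": self.response,
            "predictor": self.predictor,
            "quadratic": self.quadratic,
            "family": self.family,
            "beta_exp": dict(zip(terms, map(float, self.beta_exp))),
            "se": dict(zip(terms, map(float, self.se))),
            "wald_p": dict(zip(terms, map(float, self.wald_p))),
            "theta": float(self.theta),
            "aic": float(self.aic),
            "delta_aic": float(self.delta_aic),
            "dispersion_ratio": float(self.dispersion_ratio),
            "pearson_chi2": float(self.pearson_chi2),
            "converged": bool(self.converged),
            "n": int(self.n),
        }


def _design(y, x, quadratic: bool):
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 10:
        raise ValueError("need a 1-D response with at least 10 observations")
    if np.any(y < 0) or not np.all(np.isfinite(y)):
        raise ValueError("response values must be finite and non-negative")
    if x is None:
        return y, np.ones((y.size, 1))
    x = np.asarray(x, dtype=float)
    if x.shape != y.shape or not np.all(np.isfinite(x)):
        raise ValueError("predictor must be finite and match the response length")
    cols = [np.ones_like(x), x]
    if quadratic:
        cols.append(x**2)
        # no centering before squaring; log if the columns are near-collinear
        if abs(np.corrcoef(x, x**2)[0, 1]) > 0.999:
            log.warning("x and x^2 nearly collinear; quadratic fit may be unstable")
    return y, np.column_stack(cols)


def _result(res, family, theta, response, predictor, quadratic, y, extra_params=0):
    df_resid = int(res.df_resid)
    k = res.params.size + extra_params
    aic = 2.0 * k - 2.0 * res.llf
    return ModelFitResult(
        response=response,
        predictor=predictor,
        quadratic=quadratic,
        family=family,
        coef=np.asarray(res.params, float),
        beta_exp=np.exp(np.asarray(res.params, float)),
        se=np.asarray(res.bse, float),
        wald_p=np.asarray(res.pvalues, float),
        theta=theta,
        llf=float(res.llf),
        aic=float(aic),
        deviance=float(res.deviance),
        pearson_chi2=float(res.pearson_chi2),
        df_resid=df_resid,
        dispersion_ratio=float(res.deviance / df_resid) if df_resid > 0 else np.inf,
        converged=bool(getattr(res, "converged", True)),
        n=int(y.size),
        fitted_mu=np.asarray(res.mu, float),
        y=y,
    )


def fit_nb_glm(
    y,
    x=None,
    predictor: str = "intercept_only",
    response: str = "density",
    quadratic: bool = False,
    integer_mode: bool = False,
) -> ModelFitResult:
    """Fit a single-predictor negative-binomial GLM with log link.

    Parameters
    ----------
    y : array-like
        Non-negative response (per-km density; need not be integer).
    x : array-like, optional
        Predictor; omit for the intercept-only model.
    quadratic : bool
        Add an ``x^2`` term (hump-shaped relationships).
    integer_mode : bool
        Round the response to integers before fitting.

    Notes
    -----
    AIC counts the dispersion parameter theta, matching standard NB-GLM
    software.  Non-convergence is flagged on the result, not raised.
    """
    y, X = _design(y, x, quadratic)
    if integer_mode:
        y = np.round(y)

    def negll(log_alpha):
        fam = sm.families.NegativeBinomial(alpha=float(np.exp(log_alpha)))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=fam).fit(maxiter=100, tol=1e-8)
        except Exception:
            return np.inf
        return -res.llf

    opt = minimize_scalar(negll, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    alpha = float(np.exp(opt.x))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit(
            maxiter=100, tol=1e-8
        )
    fit = _result(
        res, "negative_binomial", 1.0 / alpha, response, predictor, quadratic, y,
        extra_params=1,
    )
    fit.converged = bool(fit.converged and opt.success)
    return fit


def fit_poisson_glm(
    y, x=None, predictor: str = "intercept_only", response: str = "density",
    quadratic: bool = False, integer_mode: bool = False,
) -> ModelFitResult:
    """Fit the Poisson counterpart (used for the overdispersion check)."""
    y, X = _design(y, x, quadratic)
    if integer_mode:
        y = np.round(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=100, tol=1e-8)
    return _result(res, "poisson", np.inf, response, predictor, quadratic, y)


@dataclass
class DispersionReport:
    pearson_chi2: float
    ratio: float
    verdict: str
    threshold: float


def overdispersion_check(fit: ModelFitResult, threshold: float = 1.5) -> DispersionReport:
    """Pearson chi-square and residual-deviance/df overdispersion diagnostic.

    The verdict is ``"overdispersed"`` when the residual deviance divided
    by the residual degrees of freedom exceeds ``threshold`` (default 1.5),
    else ``"adequate"``.
    """
    if fit.df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    verdict = "overdispersed" if fit.dispersion_ratio > threshold else "adequate"
    return DispersionReport(
        pearson_chi2=fit.pearson_chi2,
        ratio=fit.dispersion_ratio,
        verdict=verdict,
        threshold=threshold,
    )


@dataclass
class ModelSet:
    """A ranked collection of fits sharing one response."""

    response: str
    results: list

    @property
    def best(self) -> ModelFitResult:
        return self.results[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            beta = r.beta_exp
            rows.append(
                {
                    "predictor": r.predictor,
                    "delta_aic": r.delta_aic,
                    "aic": r.aic,
                    "beta": beta[1] if beta.size > 1 else beta[0],
                    "beta_sq": beta[2] if beta.size > 2 else np.nan,
                    "theta": r.theta,
                    "converged": r.converged,
                }
            )
        return pd.DataFrame(rows)


def rank_models(fits) -> ModelSet:
    """Rank fits of one response by AIC and attach delta-AIC values."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to rank")
    responses = {f.response for f in fits}
    sizes = {f.n for f in fits}
    if len(responses) > 1 or len(sizes) > 1:
        raise ValueError("fits mix responses; rank within a single model set")
    best = min(f.aic for f in fits)
    for f in fits:
        f.delta_aic = f.aic - best
    ordered = sorted(fits, key=lambda f: f.aic)
    return ModelSet(response=fits[0].response, results=ordered)


def fit_model_set(
    data: pd.DataFrame,
    response: str,
    predictors=tuple(DEFAULT_PREDICTORS),
    quadratic: bool = True,
    integer_mode: bool = False,
) -> ModelSet:
    """Fit the nine-model set for one response column of a route summary.

    Eight single-predictor NB GLMs (each with a quadratic term when
    ``quadratic`` is set) plus the intercept-only model, ranked by AIC.
    """
    y = data[response].to_numpy(dtype=float)
    fits = [
        fit_nb_glm(y, response=response, predictor="intercept_only",
                   integer_mode=integer_mode)
    ]
    for name in predictors:
        fits.append(
            fit_nb_glm(
                y,
                data[name].to_numpy(dtype=float),
                predictor=name,
                response=response,
                quadratic=quadratic,
                integer_mode=integer_mode,
            )
        )
    return rank_models(fits)
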