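"""Phenotype-on-inbreeding screening regressions.

Continuous traits are regressed on an inbreeding coefficient by ordinary
least squares; ordinal 1-3 defect scores by a proportional-odds logistic
model.  The ordinal model uses the latent-scale parameterisation

    P(Y <= k) = logistic(zeta_k - b * f)

(the R ``polr`` convention), so a *positive* b shifts probability mass toward
higher — worse — categories.  Sign conventions differ across texts; this one
makes inbreeding depression on defect scores appear as positive slopes.

These are single-predictor screens (no covariate adjustment); the full
mixed-model treatment lives in :mod:`idload.model`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel


@dataclass
class RegressionResult:
    """Slope of phenotype on inbreeding with its test statistic."""

    coefficient: float          # phenotype units per unit inbreeding
    standard_error: float
    t_or_z: float
    p_value: float
    n: int
    model_kind: str             # "linear" | "proportional_odds"
    intercept: float | None = None
    cutpoints: np.ndarray | None = None
    log_likelihood: float | None = None


def linear_depression_regression(y, f) -> RegressionResult:
    """OLS slope of a continuous phenotype on an inbreeding coefficient.

    Two-sided Student-t test of the slope against zero.
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape:
        raise ValueError("y and f must have equal length")
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(f) == 0:
        raise ValueError("degenerate predictor: inbreeding vector is constant")
    res = sm.OLS(y, sm.add_constant(f)).fit()
    return RegressionResult(
        coefficient=float(res.params[1]),
        standard_error=float(res.bse[1]),
        t_or_z=float(res.tvalues[1]),
        p_value=float(res.pvalues[1]),
        n=int(y.size),
        model_kind="linear",
        intercept=float(res.params[0]),
    )


def ordinal_nll(params: np.ndarray, y: np.ndarray, f: np.ndarray,
                k: int) -> float:
    """Negative log-likelihood of the proportional-odds model.

    ``params`` = (b, zeta_1 .. zeta_{k-1}); categories in y are 0..k-1.
    Shared with the independent optimiser used in the tests.
    """
    b = params[0]
    zeta = params[1:]
    if np.any(np.diff(zeta) <= 0):
        return np.inf
    eta = np.concatenate([[-np.inf], zeta, [np.inf]])
    upper = eta[y + 1] - b * f
    lower = eta[y] - b * f
    p = stats.logistic.cdf(upper) - stats.logistic.cdf(lower)
    if np.any(p <= 0):
        return np.inf
    return -float(np.sum(np.log(p)))


def ordinal_depression_regression(y, f, *, maxiter: int = 200
                                  ) -> RegressionResult:
    """Proportional-odds fit of ordinal scores on an inbreeding coefficient.

    Maximum likelihood via statsmodels' ordered logit (same parameterisation
    as R's ``polr``); the z statistic comes from the inverse observed
    information.
    """
    y = np.asarray(y)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape:
        raise ValueError("y and f must have equal length")
    if y.size < 10:
        raise ValueError("need at least 10 observations")
    cats = np.unique(y)
    if cats.size < 2:
        raise ValueError("only one observed category")
    if np.ptp(f) == 0:
        raise ValueError("degenerate predictor: inbreeding vector is constant")

    codes = np.searchsorted(cats, y)
    model = OrderedModel(codes, f[:, None], distr="logit")
    res = model.fit(method="bfgs", maxiter=maxiter, disp=False)
    if not res.mle_retvals.get("converged", True):
        grad = np.linalg.norm(model.score(res.params))
        raise RuntimeError(f"proportional-odds fit did not converge "
                           f"(gradient norm {grad:.3g})")
    cut = model.transform_threshold_params(res.params)[1:-1]
    return RegressionResult(
        coefficient=float(res.params[0]),
        standard_error=float(res.bse[0]),
        t_or_z=float(res.tvalues[0]),
        p_value=float(res.pvalues[0]),
        n=int(y.size),
        model_kind="proportional_odds",
        cutpoints=np.asarray(cut, dtype=float),
        log_likelihood=float(res.llf),
    )


def depression_regression(y, f, model: str) -> RegressionResult:
    """Dispatch on model kind ("linear" or "ordinal")."""
    if model == "linear":
        return linear_depression_regression(y, f)
    if model in ("ordinal", "proportional_odds"):
        return ordinal_depression_regression(y, f)
    raise ValueError(f"unknown model kind {model!r}")
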