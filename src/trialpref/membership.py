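"""Beta regression of posterior class-membership probabilities.

The third estimation stage regresses each respondent's posterior
probability of belonging to the larger preference class (class 2) on their
characteristics.  The outcome lies in [0, 1], so it is first compressed to
the open interval with the usual (y (n-1) + 1/2) / n transform, then
modelled as Beta(mu phi, (1 - mu) phi) with logit(mu) = z'gamma and a
constant precision phi.  This is the naive three-step approach: the
posterior is treated as an observed outcome, without correction for its
estimation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.othermod.betareg import BetaModel

from .initial_decision import ModelError, star_code


@dataclass
class BetaRegFit:
    """A fitted beta regression (logit mean link, constant precision)."""

    coefficients: pd.Series  # mean-model gamma over dummies (incl. const)
    precision: float  # phi > 0
    standard_errors: pd.Series
    p_values: pd.Series
    log_likelihood: float
    n_obs: int
    star_codes: pd.Series = field(default_factory=pd.Series)
    gradient_norm: float = float("nan")

    def fitted_means(self, Z: pd.DataFrame) -> np.ndarray:
        Zc = sm.add_constant(Z.astype(float), has_constant="add")
        eta = Zc.to_numpy() @ self.coefficients.loc[Zc.columns].to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


def squeeze_to_open_interval(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Compress [0, 1] outcomes into (0, 1): y' = (y (n-1) + 1/2) / n.

    Order-preserving; 0.5 is a fixed point.  ``n`` defaults to the sample
    size.
    """
    y = np.asarray(y, float)
    if np.any(y < 0) or np.any(y > 1):
        raise ModelError("outcomes must lie in [0, 1]")
    if n is None:
        n = y.size
    if n < 2:
        raise ModelError("need n >= 2 for the compression transform")
    return (y * (n - 1) + 0.5) / n


def fit_beta_regression(y: np.ndarray, Z: pd.DataFrame) -> BetaRegFit:
    """Maximum-likelihood beta regression of open-interval outcomes on Z.

    A constant column is added to the mean model; the precision model is
    intercept-only (phi constant).  Standard errors come from the inverse
    observed information; raises if the optimiser fails to converge or the
    score norm at the optimum exceeds 1e-6.
    """
    y = np.asarray(y, float)
    if np.any(y <= 0) or np.any(y >= 1):
        raise ModelError(
            "outcomes must lie strictly in (0, 1); apply "
            "squeeze_to_open_interval first"
        )
    Zc = sm.add_constant(Z.astype(float), has_constant="raise")
    if np.linalg.matrix_rank(Zc.to_numpy()) < Zc.shape[1]:
        raise ModelError("mean-model design matrix is rank deficient")
    model = BetaModel(y, Zc)
    res = model.fit(method="bfgs", maxiter=500, disp=False)
    # Newton polish: BFGS stops on the per-observation gradient scale; a few
    # Newton steps drive the full-sample score norm to machine precision.
    res = model.fit(method="newton", maxiter=50, disp=False, start_params=res.params)
    grad = np.asarray(model.score(np.asarray(res.params)))
    gnorm = float(np.linalg.norm(grad))
    if not res.mle_retvals.get("converged", True) or gnorm > 1e-6:
        raise ModelError(
            f"beta regression did not converge (score norm {gnorm:.2e}); "
            f"trace: {res.mle_retvals}"
        )
    # last parameter is the log-link precision
    phi = float(np.exp(res.params.iloc[-1]))
    mean_params = res.params.iloc[:-1]
    mean_se = res.bse.iloc[:-1]
    mean_p = res.pvalues.iloc[:-1]
    fit = BetaRegFit(
        coefficients=mean_params,
        precision=phi,
        standard_errors=mean_se,
        p_values=mean_p,
        log_likelihood=float(res.llf),
        n_obs=len(y),
        gradient_norm=gnorm,
    )
    fit.star_codes = fit.p_values.map(star_code)
    return fit


def membership_table(fit: BetaRegFit) -> pd.DataFrame:
    """Coefficient report: MLE, SE and stars per dummy.

    Positive coefficients indicate a higher likelihood of belonging to
    class 2 over class 1.
    """
    return pd.DataFrame(
        {
            "coefficient": fit.coefficients,
            "se": fit.standard_errors,
            "p_value": fit.p_values,
            "stars": fit.star_codes,
        }
    )
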