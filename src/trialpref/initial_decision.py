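"""Logistic regressions of the initial participation decision.

Three covariate variants of the model are compared: Model 1 uses all
participant-characteristic dummies; Model 2 only disease-related dummies
plus country of residence; Model 3 everything except disease-related
dummies and country.  Candidate covariates are screened for collinearity
(pairs with |Pearson r| > 0.8 drop the later column), fits are by maximum
likelihood (Newton), and out-of-sample performance is the percentage of
held-out decisions correctly predicted under stratified tenfold
cross-validation with a 0.5 probability cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import StratifiedKFold
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import DUMMY_COLUMNS, dummy_matrix

VARIANTS = ("model1_all", "model2_disease_country", "model3_except_disease_country")

DISEASE_DUMMIES = (
    "diag_ge6y",
    "conditions_ge3",
    "anemia",
    "anxiety",
    "depression",
    "diabetes",
    "heart_disease",
    "migraine",
    "multiple_sclerosis",
    "rheumatoid_arthritis",
    "cancer_lower",
    "cancer_higher",
)
COUNTRY_DUMMIES = ("country_poland", "country_china")

#: Dummies reported only in the all-characteristics variant.
MODEL1_ONLY = ("covid_vaccine", "trial_experience", "qol_ge8")

VARIANT_COLUMNS: dict[str, tuple[str, ...]] = {
    "model1_all": tuple(DUMMY_COLUMNS),
    "model2_disease_country": DISEASE_DUMMIES + COUNTRY_DUMMIES,
    "model3_except_disease_country": tuple(
        c
        for c in DUMMY_COLUMNS
        if c not in DISEASE_DUMMIES + COUNTRY_DUMMIES + MODEL1_ONLY
    ),
}


class ModelError(ValueError):
    """Raised for degenerate design matrices or failed fits."""


def star_code(p: float) -> str:
    """Significance stars: * p<0.1, ** p<0.05, *** p<0.01."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def cohen_label(r: float) -> str:
    """Cohen-style magnitude label for a correlation coefficient."""
    a = abs(r)
    if a >= 0.5:
        return "large"
    if a >= 0.3:
        return "moderate"
    if a >= 0.1:
        return "small"
    return "negligible"


@dataclass
class LogitFit:
    """A fitted initial-decision logistic regression."""

    variant: str
    coefficients: pd.Series
    standard_errors: pd.Series
    p_values: pd.Series
    log_likelihood: float
    bic: float
    predictive_validity_pct: float
    n_obs: int
    star_codes: pd.Series = field(default_factory=pd.Series)
    dropped_columns: tuple[str, ...] = ()
    cv_log: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        """Coefficient table in reporting layout (MLE, SE, stars)."""
        return pd.DataFrame(
            {
                "coefficient": self.coefficients,
                "se": self.standard_errors,
                "p_value": self.p_values,
                "stars": self.star_codes,
            }
        )


def screen_collinearity(
    X: pd.DataFrame, threshold: float = 0.8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop near-collinear columns and report all pairwise correlations.

    For every pair with |Pearson r| above ``threshold`` the later column (in
    input order) is dropped.  The report lists each pair's coefficient with
    a Cohen-style magnitude label.  Zero-variance columns are an error.
    """
    if X.shape[1] < 2:
        raise ModelError("need at least two columns to screen")
    variances = X.var(axis=0, ddof=0)
    dead = variances[variances == 0].index.tolist()
    if dead:
        raise ModelError(f"zero-variance columns: {dead}")
    corr = X.corr()
    cols = list(X.columns)
    dropped: set[str] = set()
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = float(corr.loc[a, b])
            rows.append(
                {"col_a": a, "col_b": b, "r": r, "magnitude": cohen_label(r)}
            )
            if abs(r) > threshold and a not in dropped and b not in dropped:
                dropped.add(b)
    report = pd.DataFrame(rows)
    report["dropped"] = report["col_b"].isin(dropped)
    return X.drop(columns=sorted(dropped)), report


def fit_logit(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    variant: str = "custom",
    predictive_validity: float = float("nan"),
) -> LogitFit:
    """Maximum-likelihood logistic regression with Wald inference.

    ``X`` must not contain a constant column; one is added internally and
    reported as ``const``.  Raises on perfect separation or rank deficiency.
    """
    y = np.asarray(y, float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ModelError("outcomes must be binary 0/1")
    Xc = sm.add_constant(X.astype(float), has_constant="raise")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        raise ModelError(
            f"design matrix is rank deficient ({rank} < {Xc.shape[1]})"
        )
    model = sm.Logit(y, Xc)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            res = model.fit(method="newton", disp=False, tol=1e-10, maxiter=200)
        except (np.linalg.LinAlgError, PerfectSeparationError, RuntimeWarning) as exc:
            raise ModelError(f"logit fit failed (separation?): {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ModelError("logit fit did not converge")
    k = Xc.shape[1]
    n = len(y)
    bic = k * np.log(n) - 2.0 * res.llf
    fit = LogitFit(
        variant=variant,
        coefficients=res.params,
        standard_errors=res.bse,
        p_values=res.pvalues,
        log_likelihood=float(res.llf),
        bic=float(bic),
        predictive_validity_pct=predictive_validity,
        n_obs=n,
    )
    fit.star_codes = fit.p_values.map(star_code)
    return fit


def cv_predictive_validity(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    folds: int = 10,
    rng: np.random.Generator | int | None = None,
    cutoff: float = 0.5,
) -> tuple[float, list[str]]:
    """Stratified k-fold out-of-sample classification accuracy (percent).

    The model is refit on each training split and held-out decisions are
    classified at the probability ``cutoff``.  A training fold whose outcome
    is single-class falls back to the majority rule (intercept-only model)
    and is noted in the log.
    """
    y = np.asarray(y, float)
    if len(y) < folds:
        raise ModelError("fewer observations than folds")
    seed = (
        rng
        if isinstance(rng, (int, np.integer))
        else int(np.random.default_rng(rng).integers(2**31))
    )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed))
    correct = 0
    log: list[str] = []
    Xv = X.astype(float)
    for f, (tr, te) in enumerate(skf.split(Xv, y)):
        y_tr = y[tr]
        if y_tr.min() == y_tr.max():
            p = np.full(len(te), y_tr.mean())
            log.append(f"fold {f}: single-class training outcome; majority rule")
        else:
            # Separation in a training fold is no obstacle to held-out
            # prediction (fitted probabilities just saturate), so the
            # perfect-prediction guard is disabled for CV refits.
            model = sm.Logit(y_tr, sm.add_constant(Xv.iloc[tr]))
            model.raise_on_perfect_prediction = False
            p = None
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for method in ("newton", "lbfgs"):
                    try:
                        res = model.fit(method=method, disp=False, maxiter=200)
                        p = np.asarray(
                            res.predict(
                                sm.add_constant(Xv.iloc[te], has_constant="add")
                            )
                        )
                        break
                    except Exception as exc:  # noqa: BLE001
                        log.append(f"fold {f}: {method} refit failed ({exc})")
            if p is None:
                p = np.full(len(te), y_tr.mean())
                log.append(f"fold {f}: all refits failed; majority rule")
        correct += int(((p >= cutoff).astype(float) == y[te]).sum())
    return 100.0 * correct / len(y), log


def compare_variants(
    covariates: pd.DataFrame,
    decisions: np.ndarray | pd.Series,
    variants: Mapping[str, Sequence[str]] | None = None,
    folds: int = 10,
    rng: np.random.Generator | int | None = None,
    screen_threshold: float = 0.8,
) -> tuple[dict[str, LogitFit], pd.DataFrame]:
    """Fit the three covariate variants and rank them.

    Returns the fits plus a comparison table with BIC and predictive
    validity; lower BIC ranks better, higher predictive validity ranks
    better.
    """
    variants = dict(variants or VARIANT_COLUMNS)
    D = dummy_matrix(covariates)
    rng = np.random.default_rng(rng)
    fold_seed = int(rng.integers(2**31))
    fits: dict[str, LogitFit] = {}
    rows = []
    for name, cols in variants.items():
        cols = list(cols)
        if not cols:
            raise ModelError(f"variant {name!r} requests zero covariates")
        missing = [c for c in cols if c not in D.columns]
        if missing:
            raise ModelError(f"variant {name!r}: missing covariate columns {missing}")
        X, _report = screen_collinearity(D[cols], threshold=screen_threshold)
        pv, cv_log = cv_predictive_validity(decisions, X, folds=folds, rng=fold_seed)
        fit = fit_logit(decisions, X, variant=name, predictive_validity=pv)
        fit.dropped_columns = tuple(c for c in cols if c not in X.columns)
        fit.cv_log = cv_log
        fits[name] = fit
        rows.append(
            {
                "variant": name,
                "n_params": len(fit.coefficients),
                "log_likelihood": fit.log_likelihood,
                "bic": fit.bic,
                "predictive_validity_pct": fit.predictive_validity_pct,
            }
        )
    table = pd.DataFrame(rows)
    table["bic_rank"] = table["bic"].rank(method="min").astype(int)
    table["pv_rank"] = (
        table["predictive_validity_pct"].rank(ascending=False, method="min").astype(int)
    )
    return fits, table
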