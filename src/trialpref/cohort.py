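"""Synthetic respondent cohorts with known ground truth.

The original survey data are proprietary, so every estimation stage in this
package is exercised against simulated cohorts whose generating parameters
are known.  The generator emulates the published study conditions: 487
respondents across the US, Poland and China with exact per-indication
quotas; the published covariate marginals (including a 0-24 quality-of-life
score built from six 0-4 items); large pairwise associations among country,
age group and employment induced by a Gaussian copula; a logistic model for
the initial participation decision; a two-class latent preference structure
with published class shares and switch odds ratios; and the adaptive
1-initial + 5-follow-up task sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import trial_design
from .trial_design import DesignSchema, load_schema

_DEFAULT_TRUTH_PATH = Path(__file__).parent / "data" / "default_truth.json"

#: Observed per-indication counts in the published sample of 487; used as
#: exact default quotas.  The first six groups are the screening indications
#: (every respondent carries at least one); the last four are comorbidities.
DEFAULT_QUOTAS: dict[str, int] = {
    "higher_cancer": 87,
    "lower_cancer": 96,
    "heart_disease": 122,
    "migraine": 178,
    "multiple_sclerosis": 51,
    "rheumatoid_arthritis": 134,
    "anemia": 93,
    "anxiety": 111,
    "depression": 106,
    "diabetes": 106,
}

SCREENING_INDICATIONS = (
    "higher_cancer",
    "lower_cancer",
    "heart_disease",
    "migraine",
    "multiple_sclerosis",
    "rheumatoid_arthritis",
)
COMORBIDITIES = ("anemia", "anxiety", "depression", "diabetes")

DEFAULT_N = 487

#: Marginal category frequencies.  Published proportions where available;
#: values without a published marginal (living alone, dependents, COVID
#: vaccination, time since diagnosis, quality of life vs last year) were
#: fixed once at plausible rates.
DEFAULT_MARGINALS: dict[str, dict] = {
    "country": {"US": 161 / 487, "Poland": 169 / 487, "China": 157 / 487},
    "sex_female": 0.52,
    "education": {
        "less_than_elementary": 1 / 487,
        "elementary": 75 / 487,
        "high_school": 49 / 487,
        "college": 242 / 487,
        "postgraduate": 118 / 487,
        "other": 2 / 487,
    },
    "employment": {
        "full_time": 276 / 487,
        "part_time": 31 / 487,
        "hourly": 19 / 487,
        "not_working": 161 / 487,
    },
    "living_alone": 0.25,
    "dependents": 0.40,
    "trial_experience": 160 / 487,
    "covid_vaccine": 0.70,
    "time_since_diag_6plus": 0.45,
    "n_prior_treatments": {
        "0": 41 / 487,
        "1-2": 146 / 487,
        "3-4": 132 / 487,
        "5+": 168 / 487,
    },
    "affordability": {"easily": 168 / 487, "can": 272 / 487, "struggle": 47 / 487},
    "side_effect_experience": {
        "none": 155 / 487,
        "mild": 249 / 487,
        "severe": 83 / 487,
    },
    # Six QoL items, published as three bands (0-1 / 2 / 3-4); the outer
    # bands are split 60/40 between their two scores.
    "qol_items": {
        "fatigue": [209 / 487, 129 / 487, 149 / 487],
        "mobility": [336 / 487, 84 / 487, 67 / 487],
        "pain": [244 / 487, 121 / 487, 122 / 487],
        "anxious": [276 / 487, 87 / 487, 124 / 487],
        "social": [282 / 487, 98 / 487, 107 / 487],
        "usual": [310 / 487, 107 / 487, 70 / 487],
    },
    "qol_band_split": [0.6, 0.4],
    "qol_vs_last_year_improve": 0.20,
    "longevity": {
        "high": 261 / 487,
        "neutral": 125 / 487,
        "low": 80 / 487,
        "not_sure": 21 / 487,
    },
    "future_qol_improve": 91 / 487,
    "trust": [0.03, 0.05, 0.07, 0.45, 0.40],
    "altruism": [0.04, 0.06, 0.07, 0.45, 0.38],
    "age": {"mean": 47.0, "sd": 17.0, "min": 18.0, "max": 95.0},
}

#: Canonical dummy columns of the participant-characteristics models, in
#: reporting order (disease, treatment, health, sociodemographic,
#: attitudinal, other).
DUMMY_COLUMNS: tuple[str, ...] = (
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
    "treatments_ge3",
    "afford_can",
    "afford_struggle",
    "side_effects_mild",
    "side_effects_severe",
    "covid_vaccine",
    "trial_experience",
    "fatigue_ge2",
    "mobility_ge2",
    "pain_ge2",
    "anxious_ge2",
    "social_ge3",
    "usual_ge3",
    "qol_ge8",
    "qol_worse_vs_last_year",
    "longevity_low",
    "future_qol_same_worse",
    "age_51_65",
    "age_ge66",
    "female",
    "country_poland",
    "country_china",
    "no_paid_job",
    "university",
    "living_alone_no",
    "dependents_no",
    "high_trust",
    "high_altruism",
    "survey_version_2",
)


class CohortError(ValueError):
    """Raised for infeasible cohort configurations."""


@dataclass(frozen=True)
class TrueParameters:
    """Generating parameters of a synthetic cohort."""

    class_shares: tuple[float, ...]
    reference_switch_odds: tuple[float, ...]
    odds_ratios: Mapping[str, tuple[float, ...]]  # attr -> per-class OR
    initial_intercept: float
    initial_coefficients: Mapping[str, float]
    membership_intercept: float
    membership_coefficients: Mapping[str, float]
    correlation_targets: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shares = np.asarray(self.class_shares, float)
        if np.any(shares <= 0) or np.any(shares >= 1) or abs(shares.sum() - 1) > 1e-9:
            raise CohortError("class shares must lie in (0,1) and sum to 1")
        for attr, ors in self.odds_ratios.items():
            if len(ors) != len(shares):
                raise CohortError(f"odds ratios for {attr!r}: wrong class count")
            if np.any(np.asarray(ors) <= 0):
                raise CohortError(f"odds ratios for {attr!r} must be positive")

    @property
    def n_classes(self) -> int:
        return len(self.class_shares)


def load_truth(config: str | Path | Mapping | None = None) -> TrueParameters:
    """Load generating truth parameters (shipped defaults when ``None``)."""
    if config is None:
        config = _DEFAULT_TRUTH_PATH
    if isinstance(config, (str, Path)):
        raw = json.loads(Path(config).read_text(encoding="utf-8"))
    else:
        raw = dict(config)
    return TrueParameters(
        class_shares=tuple(raw["class_shares"]),
        reference_switch_odds=tuple(raw["reference_switch_odds"]),
        odds_ratios={k: tuple(v) for k, v in raw["odds_ratios"].items()},
        initial_intercept=float(raw["initial_decision"]["intercept"]),
        initial_coefficients=dict(raw["initial_decision"]["coefficients"]),
        membership_intercept=float(raw["membership"]["intercept"]),
        membership_coefficients=dict(raw["membership"]["coefficients"]),
        correlation_targets=dict(raw.get("correlation_targets", {})),
    )


# ---------------------------------------------------------------------------
# Gaussian copula for (country, age group, employment)
# ---------------------------------------------------------------------------


def _ordinal_cutpoints(probs: Sequence[float]) -> np.ndarray:
    """Standard-normal thresholds splitting categories with given masses."""
    cum = np.cumsum(probs)[:-1]
    return stats.norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12))


def _code_moments(probs: Sequence[float]) -> tuple[float, float]:
    codes = np.arange(len(probs))
    p = np.asarray(probs, float)
    mu = float(codes @ p)
    var = float((codes**2) @ p - mu**2)
    return mu, var


def _discretized_pearson(rho: float, probs_x, probs_y) -> float:
    """Pearson correlation of ordinal codes under a latent normal rho."""
    tx = np.concatenate(([-np.inf], _ordinal_cutpoints(probs_x), [np.inf]))
    ty = np.concatenate(([-np.inf], _ordinal_cutpoints(probs_y), [np.inf]))
    cov = np.array([[1.0, rho], [rho, 1.0]])
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True)

    def rect(a0, a1, b0, b1):
        # P(a0 < X <= a1, b0 < Y <= b1) via inclusion-exclusion on the CDF
        def cdf(a, b):
            if np.isinf(a) and a < 0 or np.isinf(b) and b < 0:
                return 0.0
            aa = 8.0 if np.isinf(a) else a
            bb = 8.0 if np.isinf(b) else b
            return float(mvn.cdf([aa, bb]))

        return cdf(a1, b1) - cdf(a0, b1) - cdf(a1, b0) + cdf(a0, b0)

    exy = 0.0
    for i in range(len(probs_x)):
        for j in range(len(probs_y)):
            if i == 0 or j == 0:
                continue  # zero codes contribute nothing to E[XY]
            exy += i * j * rect(tx[i], tx[i + 1], ty[j], ty[j + 1])
    mux, varx = _code_moments(probs_x)
    muy, vary = _code_moments(probs_y)
    return (exy - mux * muy) / np.sqrt(varx * vary)


def latent_correlation(target: float, probs_x, probs_y) -> float:
    """Invert the discretisation attenuation: latent rho hitting ``target``.

    Solves for the bivariate-normal correlation whose discretised ordinal
    codes have Pearson correlation ``target``.  Raises if the target exceeds
    what the marginals allow.
    """
    if not -1 < target < 1:
        raise CohortError(f"correlation target {target} outside (-1, 1)")
    if target == 0:
        return 0.0
    hi = _discretized_pearson(0.999, probs_x, probs_y)
    lo = _discretized_pearson(-0.999, probs_x, probs_y)
    if not lo < target < hi:
        raise CohortError(
            f"correlation target {target} unattainable for these marginals "
            f"(attainable range [{lo:.3f}, {hi:.3f}])"
        )
    return float(
        optimize.brentq(
            lambda r: _discretized_pearson(r, probs_x, probs_y) - target,
            -0.999,
            0.999,
            xtol=1e-6,
        )
    )


def _age_group_probs(age_cfg: Mapping[str, float]) -> np.ndarray:
    """Age-group masses implied by the truncated-normal age model."""
    a = (age_cfg["min"] - age_cfg["mean"]) / age_cfg["sd"]
    b = (age_cfg["max"] - age_cfg["mean"]) / age_cfg["sd"]
    dist = stats.truncnorm(a, b, loc=age_cfg["mean"], scale=age_cfg["sd"])
    edges = [age_cfg["min"], 36.0, 51.0, 66.0, age_cfg["max"]]
    cdf = dist.cdf(edges)
    return np.diff(cdf) / (cdf[-1] - cdf[0])


def _copula_matrix(
    marginals: Mapping, targets: Mapping[str, float]
) -> np.ndarray:
    """3x3 latent correlation matrix for (country, age, employment)."""
    p_country = list(marginals["country"].values())
    p_age = _age_group_probs(marginals["age"])
    p_emp = list(marginals["employment"].values())
    pairs = {
        ("country", "age_group"): (p_country, p_age),
        ("age_group", "employment"): (p_age, p_emp),
        ("country", "employment"): (p_country, p_emp),
    }
    idx = {"country": 0, "age_group": 1, "employment": 2}
    R = np.eye(3)
    for key, rho_target in targets.items():
        a, b = key.split("~")
        pair = (a, b) if (a, b) in pairs else (b, a)
        if pair not in pairs:
            raise CohortError(f"unsupported correlation pair {key!r}")
        rho = latent_correlation(rho_target, *pairs[pair])
        i, j = idx[pair[0]], idx[pair[1]]
        R[i, j] = R[j, i] = rho
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() < -1e-10:
        raise CohortError(
            "latent correlation matrix for (country, age_group, employment) "
            "is not positive semi-definite; relax one of the pairwise targets"
        )
    return R


def _categorical_from_uniform(u: np.ndarray, categories, probs) -> np.ndarray:
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    idx = np.searchsorted(cum, u, side="right")
    return np.asarray(categories, object)[np.clip(idx, 0, len(cum) - 1)]


# ---------------------------------------------------------------------------
# Exact-quota indication assignment
# ---------------------------------------------------------------------------


def scale_quotas(n: int, quotas: Mapping[str, int] | None = None) -> dict[str, int]:
    """Scale the default 487-respondent quotas proportionally to ``n``."""
    quotas = dict(DEFAULT_QUOTAS if quotas is None else quotas)
    if n == DEFAULT_N and quotas == DEFAULT_QUOTAS:
        return quotas
    factor = n / DEFAULT_N
    return {k: max(1, int(round(v * factor))) for k, v in quotas.items()}


def _assign_indications(
    n: int, quotas: Mapping[str, int], rng: np.random.Generator
) -> pd.DataFrame:
    """Membership matrix meeting every per-indication count exactly.

    Screening indications are distributed so that each respondent carries at
    least one (quota-defining) indication; extra memberships beyond the first
    land on uniformly chosen respondents.  Higher- and lower-mortality cancer
    are kept disjoint so that the overall cancer count is their sum.
    """
    for k, c in quotas.items():
        if c > n:
            raise CohortError(f"quota for {k!r} ({c}) exceeds cohort size {n}")
    screening_total = sum(quotas[k] for k in SCREENING_INDICATIONS if k in quotas)
    if screening_total < n:
        raise CohortError(
            "screening-indication quotas sum to fewer memberships than "
            "respondents; every respondent needs at least one"
        )
    member = {k: np.zeros(n, bool) for k in quotas}
    covered = np.zeros(n, bool)
    order = sorted(
        [k for k in SCREENING_INDICATIONS if k in quotas],
        key=lambda k: -quotas[k],
    )
    for k in order:
        need = quotas[k]
        if k == "lower_cancer":
            forbidden = member.get("higher_cancer", np.zeros(n, bool))
        elif k == "higher_cancer":
            forbidden = member.get("lower_cancer", np.zeros(n, bool))
        else:
            forbidden = np.zeros(n, bool)
        uncovered = np.flatnonzero(~covered & ~forbidden)
        take = min(need, len(uncovered))
        picked = rng.choice(uncovered, size=take, replace=False)
        member[k][picked] = True
        need -= take
        if need:
            rest = np.flatnonzero(covered & ~member[k] & ~forbidden)
            if len(rest) < need:
                raise CohortError(f"cannot satisfy quota for {k!r}")
            member[k][rng.choice(rest, size=need, replace=False)] = True
        covered |= member[k]
    if not covered.all():
        raise CohortError("quota assignment left respondents without indication")
    for k in COMORBIDITIES:
        if k in quotas:
            picked = rng.choice(n, size=quotas[k], replace=False)
            member[k][picked] = True
    return pd.DataFrame({f"ind_{k}": v.astype(int) for k, v in member.items()})


# ---------------------------------------------------------------------------
# Covariate sampling
# ---------------------------------------------------------------------------


def sample_covariates(
    n: int = DEFAULT_N,
    quotas: Mapping[str, int] | None = None,
    correlation_targets: Mapping[str, float] | None = None,
    marginals: Mapping | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw a respondent covariate table.

    Indication quotas are met exactly (defaults scale the published counts
    to ``n``).  Country, age group and employment are drawn jointly through
    a Gaussian copula calibrated so the Pearson correlations of their
    ordinal codes hit ``correlation_targets`` (defaults: 0.63 country-age,
    0.61 age-employment, 0.54 country-employment).  All other covariates are
    sampled independently from their marginals.
    """
    rng = np.random.default_rng(rng)
    m = DEFAULT_MARGINALS if marginals is None else marginals
    if correlation_targets is None:
        correlation_targets = load_truth().correlation_targets

    R = _copula_matrix(m, correlation_targets)
    z = rng.multivariate_normal(np.zeros(3), R, size=n, method="cholesky")
    u = stats.norm.cdf(z)

    country = _categorical_from_uniform(
        u[:, 0], list(m["country"]), list(m["country"].values())
    )
    age_cfg = m["age"]
    a = (age_cfg["min"] - age_cfg["mean"]) / age_cfg["sd"]
    b = (age_cfg["max"] - age_cfg["mean"]) / age_cfg["sd"]
    age_dist = stats.truncnorm(a, b, loc=age_cfg["mean"], scale=age_cfg["sd"])
    age_years = np.floor(age_dist.ppf(np.clip(u[:, 1], 1e-12, 1 - 1e-12))).astype(int)
    age_group = pd.cut(
        age_years,
        bins=[0, 35, 50, 65, 200],
        labels=["18-35", "36-50", "51-65", "66+"],
    ).astype(str)
    employment = _categorical_from_uniform(
        u[:, 2], list(m["employment"]), list(m["employment"].values())
    )

    df = pd.DataFrame(
        {
            "respondent_id": np.arange(n),
            "country": country,
            "age_years": age_years,
            "age_group": age_group,
            "employment": employment,
        }
    )
    df["sex"] = np.where(rng.random(n) < m["sex_female"], "female", "male")
    df["education"] = _categorical_from_uniform(
        rng.random(n), list(m["education"]), list(m["education"].values())
    )
    df["living_alone"] = (rng.random(n) < m["living_alone"]).astype(int)
    df["dependents"] = (rng.random(n) < m["dependents"]).astype(int)

    df = pd.concat([df, _assign_indications(n, scale_quotas(n, quotas), rng)], axis=1)
    ind_cols = [c for c in df.columns if c.startswith("ind_")]
    df["n_conditions"] = df[ind_cols].sum(axis=1)

    df["time_since_diagnosis_group"] = np.where(
        rng.random(n) < m["time_since_diag_6plus"], "6+", "0-5"
    )
    df["n_prior_treatments"] = _categorical_from_uniform(
        rng.random(n),
        list(m["n_prior_treatments"]),
        list(m["n_prior_treatments"].values()),
    )
    df["affordability"] = _categorical_from_uniform(
        rng.random(n), list(m["affordability"]), list(m["affordability"].values())
    )
    df["side_effect_experience"] = _categorical_from_uniform(
        rng.random(n),
        list(m["side_effect_experience"]),
        list(m["side_effect_experience"].values()),
    )
    df["trial_experience"] = (rng.random(n) < m["trial_experience"]).astype(int)
    df["covid_vaccine"] = (rng.random(n) < m["covid_vaccine"]).astype(int)

    lo, hi = m["qol_band_split"]
    for item, bands in m["qol_items"].items():
        p = [bands[0] * lo, bands[0] * hi, bands[1], bands[2] * lo, bands[2] * hi]
        df[f"qol_{item}"] = _categorical_from_uniform(
            rng.random(n), [0, 1, 2, 3, 4], p
        ).astype(int)
    qol_cols = [f"qol_{item}" for item in m["qol_items"]]
    df["qol_total"] = df[qol_cols].sum(axis=1)

    df["qol_vs_last_year"] = np.where(
        rng.random(n) < m["qol_vs_last_year_improve"], "improve", "same_worse"
    )
    df["self_perceived_longevity"] = _categorical_from_uniform(
        rng.random(n), list(m["longevity"]), list(m["longevity"].values())
    )
    df["future_qol"] = np.where(
        rng.random(n) < m["future_qol_improve"], "improve", "same_worse"
    )
    df["trust"] = _categorical_from_uniform(
        rng.random(n), [1, 2, 3, 4, 5], m["trust"]
    ).astype(int)
    df["altruism"] = _categorical_from_uniform(
        rng.random(n), [1, 2, 3, 4, 5], m["altruism"]
    ).astype(int)
    df["high_trust"] = (df["trust"] >= 4).astype(int)
    df["high_altruism"] = (df["altruism"] >= 4).astype(int)
    # Provisional 50/50 arm; generate_cohort overwrites it with the recorded
    # randomisation arm of the initial task's two-level attributes.
    df["survey_version"] = rng.integers(1, 3, size=n)
    return df


def ordinal_codes(covariates: pd.DataFrame) -> pd.DataFrame:
    """Ordinal integer codes for the copula-linked covariates."""
    country_order = {"US": 0, "Poland": 1, "China": 2}
    age_order = {"18-35": 0, "36-50": 1, "51-65": 2, "66+": 3}
    emp_order = {"full_time": 0, "part_time": 1, "hourly": 2, "not_working": 3}
    return pd.DataFrame(
        {
            "country": covariates["country"].map(country_order),
            "age_group": covariates["age_group"].map(age_order),
            "employment": covariates["employment"].map(emp_order),
        }
    )


def dummy_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Build the canonical dummy design matrix from a covariate table.

    Reference levels follow the published coding: the constant represents
    the all-references respondent, and each dummy is the difference from its
    reference level.
    """
    c = covariates
    d = pd.DataFrame(index=c.index)
    d["diag_ge6y"] = (c["time_since_diagnosis_group"] == "6+").astype(int)
    d["conditions_ge3"] = (c["n_conditions"] >= 3).astype(int)
    for name in ("anemia", "anxiety", "depression", "diabetes"):
        d[name] = c[f"ind_{name}"]
    d["heart_disease"] = c["ind_heart_disease"]
    d["migraine"] = c["ind_migraine"]
    d["multiple_sclerosis"] = c["ind_multiple_sclerosis"]
    d["rheumatoid_arthritis"] = c["ind_rheumatoid_arthritis"]
    d["cancer_lower"] = c["ind_lower_cancer"]
    d["cancer_higher"] = c["ind_higher_cancer"]
    d["treatments_ge3"] = c["n_prior_treatments"].isin(["3-4", "5+"]).astype(int)
    d["afford_can"] = (c["affordability"] == "can").astype(int)
    d["afford_struggle"] = (c["affordability"] == "struggle").astype(int)
    d["side_effects_mild"] = (c["side_effect_experience"] == "mild").astype(int)
    d["side_effects_severe"] = (c["side_effect_experience"] == "severe").astype(int)
    d["covid_vaccine"] = c["covid_vaccine"]
    d["trial_experience"] = c["trial_experience"]
    d["fatigue_ge2"] = (c["qol_fatigue"] >= 2).astype(int)
    d["mobility_ge2"] = (c["qol_mobility"] >= 2).astype(int)
    d["pain_ge2"] = (c["qol_pain"] >= 2).astype(int)
    d["anxious_ge2"] = (c["qol_anxious"] >= 2).astype(int)
    d["social_ge3"] = (c["qol_social"] >= 3).astype(int)
    d["usual_ge3"] = (c["qol_usual"] >= 3).astype(int)
    d["qol_ge8"] = (c["qol_total"] >= 8).astype(int)
    d["qol_worse_vs_last_year"] = (c["qol_vs_last_year"] == "same_worse").astype(int)
    d["longevity_low"] = (c["self_perceived_longevity"] == "low").astype(int)
    d["future_qol_same_worse"] = (c["future_qol"] == "same_worse").astype(int)
    d["age_51_65"] = (c["age_group"] == "51-65").astype(int)
    d["age_ge66"] = (c["age_group"] == "66+").astype(int)
    d["female"] = (c["sex"] == "female").astype(int)
    d["country_poland"] = (c["country"] == "Poland").astype(int)
    d["country_china"] = (c["country"] == "China").astype(int)
    d["no_paid_job"] = (c["employment"] == "not_working").astype(int)
    d["university"] = c["education"].isin(["college", "postgraduate"]).astype(int)
    d["living_alone_no"] = 1 - c["living_alone"]
    d["dependents_no"] = 1 - c["dependents"]
    d["high_trust"] = c["high_trust"]
    d["high_altruism"] = c["high_altruism"]
    d["survey_version_2"] = (c["survey_version"] == 2).astype(int)
    return d[list(DUMMY_COLUMNS)]


def _linear_predictor(
    covariates: pd.DataFrame, intercept: float, coefficients: Mapping[str, float]
) -> np.ndarray:
    d = dummy_matrix(covariates)
    eta = np.full(len(d), float(intercept))
    for name, beta in coefficients.items():
        if name not in d.columns:
            raise CohortError(f"unknown covariate dummy {name!r} in coefficients")
        eta += beta * d[name].to_numpy(float)
    return eta


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def assign_class(
    covariates: pd.DataFrame,
    membership_coefficients: Mapping[str, float] | None = None,
    intercept: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw latent class labels (1 or 2) from the membership logit model.

    P(class 2) follows a logistic model over the canonical dummies; with the
    shipped defaults the marginal class-2 share is calibrated to 0.639.
    """
    rng = np.random.default_rng(rng)
    if membership_coefficients is None or intercept is None:
        truth = load_truth()
        if membership_coefficients is None:
            membership_coefficients = truth.membership_coefficients
        if intercept is None:
            intercept = truth.membership_intercept
    p2 = _sigmoid(_linear_predictor(covariates, intercept, membership_coefficients))
    return np.where(rng.random(len(p2)) < p2, 2, 1)


def simulate_initial_decision(
    covariates: pd.DataFrame,
    coefficients: Mapping[str, float] | None = None,
    intercept: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw the initial participation decision (True = willing).

    With the shipped defaults the marginal acceptance rate is calibrated to
    0.71.
    """
    rng = np.random.default_rng(rng)
    if coefficients is None or intercept is None:
        truth = load_truth()
        if coefficients is None:
            coefficients = truth.initial_coefficients
        if intercept is None:
            intercept = truth.initial_intercept
    p = _sigmoid(_linear_predictor(covariates, intercept, coefficients))
    return rng.random(len(p)) < p


def switch_probability(
    truth: TrueParameters, class_label: int, attribute: str, schema: DesignSchema
) -> float:
    """Closed-form switch probability for one class and modified attribute."""
    c = class_label - 1
    log_odds = np.log(truth.reference_switch_odds[c])
    if attribute != schema.reference:
        log_odds += np.log(truth.odds_ratios[attribute][c])
    return float(_sigmoid(np.array(log_odds)))


def simulate_switches(
    class_labels: np.ndarray,
    modified_attributes: np.ndarray,
    truth: TrueParameters,
    schema: DesignSchema,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw switch indicators for an (n_respondents, 5) attribute array.

    switch ~ Bernoulli(sigma(alpha_c + beta_{c,m})) where alpha_c is the log
    reference-attribute switch odds of the respondent's class and
    beta_{c,m} the log odds ratio of the modified attribute.
    """
    rng = np.random.default_rng(rng)
    class_labels = np.asarray(class_labels)
    if np.any(class_labels < 1) or np.any(class_labels > truth.n_classes):
        raise CohortError("respondent without a valid class label")
    modified = np.asarray(modified_attributes, object)
    alpha = np.log(np.asarray(truth.reference_switch_odds))[class_labels - 1]
    beta = np.zeros_like(alpha, shape=modified.shape)
    log_or = {
        attr: np.log(np.asarray(ors)) for attr, ors in truth.odds_ratios.items()
    }
    for attr in np.unique(modified):
        if attr == schema.reference:
            continue
        if attr not in log_or:
            raise CohortError(f"no odds ratio specified for attribute {attr!r}")
        mask = modified == attr
        rows = np.nonzero(mask)[0] if modified.ndim == 1 else np.nonzero(mask)[0]
        beta[mask] = log_or[attr][class_labels[rows] - 1]
    p = _sigmoid(alpha[:, None] + beta if modified.ndim == 2 else alpha + beta)
    return rng.random(p.shape) < p


# ---------------------------------------------------------------------------
# Full cohort generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """A fully simulated study: covariates, task-level responses, and truth."""

    covariates: pd.DataFrame
    responses: pd.DataFrame  # long format, one row per (respondent, task)
    truth: TrueParameters
    class_labels: np.ndarray
    seed: int

    def to_csv(self, outdir: str | Path, header_comment: str | None = None) -> dict:
        """Write covariates/responses CSVs and a truth JSON; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "covariates": outdir / "covariates.csv",
            "responses": outdir / "responses.csv",
            "truth": outdir / "truth.json",
        }
        prefix = f"# {header_comment}\n" if header_comment else ""
        cov = self.covariates.copy()
        cov["true_class"] = self.class_labels
        for key, df in (("covariates", cov), ("responses", self.responses)):
            with open(paths[key], "w", encoding="utf-8") as fh:
                fh.write(prefix)
                df.to_csv(fh, index=False)
        truth_dict = {
            "seed": self.seed,
            "class_shares": list(self.truth.class_shares),
            "reference_switch_odds": list(self.truth.reference_switch_odds),
            "odds_ratios": {k: list(v) for k, v in self.truth.odds_ratios.items()},
        }
        paths["truth"].write_text(
            json.dumps(truth_dict, indent=1), encoding="utf-8"
        )
        return paths


def generate_cohort(
    config: Mapping | None = None, seed: int = 0
) -> SyntheticCohort:
    """Simulate a complete adaptive-survey study with known truth.

    ``config`` keys (all optional): ``n`` (default 487), ``quotas``,
    ``truth`` (mapping or path), ``schema`` (mapping or path),
    ``correlation_targets``.  Identical (config, seed) pairs produce
    identical cohorts.
    """
    config = dict(config or {})
    n = int(config.get("n", DEFAULT_N))
    truth = (
        config["truth"]
        if isinstance(config.get("truth"), TrueParameters)
        else load_truth(config.get("truth"))
    )
    schema = (
        config["schema"]
        if isinstance(config.get("schema"), DesignSchema)
        else load_schema(config.get("schema"))
    )
    rng = np.random.default_rng(seed)
    covariates = sample_covariates(
        n=n,
        quotas=config.get("quotas"),
        correlation_targets=config.get(
            "correlation_targets", truth.correlation_targets
        ),
        rng=rng,
    )

    # Initial profiles: the randomisation arm of the two-level attributes is
    # recorded; the arm of the first two-level attribute defines the survey
    # version covariate.
    first_two_level = next(a.name for a in schema.attributes if a.n_levels == 2)
    initial_profiles = [trial_design.build_initial_profile(schema, rng) for _ in range(n)]
    covariates["survey_version"] = np.array(
        [1 + p.levels[first_two_level] for p in initial_profiles]
    )

    decisions = simulate_initial_decision(
        covariates,
        truth.initial_coefficients,
        truth.initial_intercept,
        rng=rng,
    )
    class_labels = assign_class(
        covariates,
        truth.membership_coefficients,
        truth.membership_intercept,
        rng=rng,
    )

    followups = [
        trial_design.generate_followups(schema, prof, bool(dec), rng)
        for prof, dec in zip(initial_profiles, decisions)
    ]
    modified = np.array(
        [[t.modified_attribute for t in tasks] for tasks in followups], object
    )
    switches = simulate_switches(class_labels, modified, truth, schema, rng=rng)

    rows: list[dict] = []
    for i in range(n):
        initial_task = trial_design.ChoiceTask(0, initial_profiles[i])
        task_decisions = [bool(decisions[i])] + [
            bool(decisions[i]) != bool(s) for s in switches[i]
        ]
        rows.extend(
            trial_design.tasks_to_records(
                i, initial_task, followups[i], task_decisions, schema
            )
        )
    responses = pd.DataFrame(rows)
    return SyntheticCohort(
        covariates=covariates,
        responses=responses,
        truth=truth,
        class_labels=class_labels,
        seed=seed,
    )
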