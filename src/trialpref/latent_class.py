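"""Latent-class binary logit on the five adaptive follow-up tasks.

Respondents are modelled as a finite mixture of C preference classes.
Within class c, the probability of switching the initial participation
decision when attribute m is modified is

    p_cm = sigma(alpha_c + beta_cm),

where alpha_c is the log odds of switching when the reference attribute
(transport provision) is modified and beta_cm is the log odds ratio of
attribute m relative to that reference (beta fixed at 0 for the reference).
Each respondent contributes five conditionally independent Bernoulli
observations on five distinct attributes, so the marginal likelihood of
respondent i is

    L_i = sum_c pi_c * prod_t p_{c,m_it}^{s_it} (1 - p_{c,m_it})^{1-s_it}.

Estimation is by EM with multiple random starts.  Because the switch model
is saturated in the modified-attribute indicators, the weighted logistic
M-step has a closed form: the class-specific switch probability of each
attribute cell is its responsibility-weighted empirical rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logit, logsumexp

from .trial_design import DesignSchema, load_schema

N_TASKS = 5

_P_CLIP = 1e-10  # caps |logit| at ~23 when a weighted cell is pure
_SHARE_FLOOR = 1e-4


class LCLError(ValueError):
    """Raised for malformed latent-class inputs or failed estimation."""


@dataclass(frozen=True)
class LCLData:
    """Switch indicators and modified-attribute codes, five per respondent.

    ``codes`` holds integers in 0..K-1 where code 0 is the reference
    attribute and codes 1..K-1 index the non-reference attributes in schema
    order.  Within a respondent the five codes are pairwise distinct.
    """

    switches: np.ndarray  # (n, 5) in {0, 1}
    codes: np.ndarray  # (n, 5) ints
    attribute_names: tuple[str, ...]  # length K, names[0] = reference
    respondent_ids: np.ndarray

    def __post_init__(self) -> None:
        s, m = np.asarray(self.switches), np.asarray(self.codes)
        if s.shape != m.shape or s.ndim != 2 or s.shape[1] != N_TASKS:
            raise LCLError("switches and codes must both be (n, 5)")
        if not np.isin(s, (0, 1)).all():
            raise LCLError("switch indicators must be 0/1")
        if (np.sort(m, axis=1)[:, 1:] == np.sort(m, axis=1)[:, :-1]).any():
            raise LCLError("modified attributes must be distinct within respondent")

    @property
    def n_respondents(self) -> int:
        return self.switches.shape[0]

    @property
    def n_attributes(self) -> int:
        return len(self.attribute_names)


@dataclass
class LCLFit:
    """A fitted latent-class logit."""

    n_classes: int
    class_shares: np.ndarray  # (C,)
    alphas: np.ndarray  # (C,) log reference switch odds
    betas: np.ndarray  # (C, K-1) log ORs vs reference
    log_likelihood: float
    bic: float
    posterior: np.ndarray  # (n, C)
    attribute_names: tuple[str, ...]
    n_starts: int
    convergence_log: list[str] = field(default_factory=list)
    loglik_trace: list[np.ndarray] = field(default_factory=list)
    beta_se: np.ndarray | None = None
    alpha_se: np.ndarray | None = None
    share_se: np.ndarray | None = None

    def params_eta(self) -> np.ndarray:
        """(C, K) per-class cell logits: eta[c, 0]=alpha_c, else alpha+beta."""
        eta = np.empty((self.n_classes, len(self.attribute_names)))
        eta[:, 0] = self.alphas
        eta[:, 1:] = self.alphas[:, None] + self.betas
        return eta


def build_lcl_data(
    responses: pd.DataFrame, schema: DesignSchema | None = None
) -> LCLData:
    """Assemble estimation data from a long-format responses table.

    Requires one initial task (``task_index == 0``) and exactly five
    follow-ups per respondent.  The switch indicator is 1 iff the follow-up
    decision differs from that respondent's initial decision.
    """
    schema = schema or load_schema()
    names = (schema.reference, *schema.non_reference_names())
    code_of = {name: k for k, name in enumerate(names)}

    required = {"respondent_id", "task_index", "modified_attribute", "decision"}
    missing = required - set(responses.columns)
    if missing:
        raise LCLError(f"responses table missing columns {sorted(missing)}")
    if responses["decision"].isna().any():
        raise LCLError("missing decision in responses table")

    initial = responses[responses["task_index"] == 0].set_index("respondent_id")[
        "decision"
    ]
    follow = responses[responses["task_index"] > 0]
    counts = follow.groupby("respondent_id").size()
    bad = counts[counts != N_TASKS]
    if len(bad):
        raise LCLError(
            f"respondents with != 5 follow-ups: {list(bad.index[:5])}"
        )
    rids = np.asarray(sorted(initial.index))
    if not set(counts.index) == set(rids):
        raise LCLError("initial and follow-up respondent sets differ")

    follow = follow.sort_values(["respondent_id", "task_index"])
    switches = (
        follow["decision"].to_numpy(int)
        != follow["respondent_id"].map(initial).to_numpy(int)
    ).astype(int)
    try:
        codes = follow["modified_attribute"].map(code_of).to_numpy()
    except Exception as exc:  # pragma: no cover
        raise LCLError(f"unknown modified attribute: {exc}") from exc
    if pd.isna(codes).any():
        unknown = sorted(
            set(follow["modified_attribute"]) - set(code_of)
        )
        raise LCLError(f"unknown modified attributes {unknown}")
    return LCLData(
        switches=switches.reshape(-1, N_TASKS),
        codes=codes.astype(int).reshape(-1, N_TASKS),
        attribute_names=names,
        respondent_ids=rids,
    )


def _class_logliks(
    data: LCLData, eta: np.ndarray
) -> np.ndarray:
    """(n, C) per-respondent conditional log-likelihoods."""
    # eta: (C, K); cell logits looked up per task
    eta_tasks = eta[:, data.codes]  # (C, n, 5)
    s = data.switches[None, :, :]
    # log sigma(eta) = -log1p(exp(-eta)); stable via logaddexp
    ll = -np.logaddexp(0.0, -eta_tasks) * s - np.logaddexp(0.0, eta_tasks) * (1 - s)
    return ll.sum(axis=2).T  # (n, C)


def lcl_loglik(
    class_shares: Sequence[float],
    alphas: Sequence[float],
    betas: np.ndarray,
    data: LCLData,
) -> float:
    """Mixture log-likelihood, log-sum-exp stabilised.

    sum_i log sum_c pi_c prod_t Bernoulli(s_it; sigma(alpha_c + beta_c,m)).
    """
    pi = np.asarray(class_shares, float)
    if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise LCLError("class shares must lie on the simplex")
    alphas = np.atleast_1d(np.asarray(alphas, float))
    betas = np.atleast_2d(np.asarray(betas, float))
    eta = np.concatenate([alphas[:, None], alphas[:, None] + betas], axis=1)
    ll = _class_logliks(data, eta)
    with np.errstate(divide="ignore"):
        return float(logsumexp(ll + np.log(pi)[None, :], axis=1).sum())


def _m_step(data: LCLData, W: np.ndarray, eta_prev: np.ndarray) -> np.ndarray:
    """Exact weighted-logistic M-step for the saturated switch model.

    The MLE cell probability equals the responsibility-weighted switch rate
    per (class, attribute) cell; empty cells keep their previous logit.
    """
    n, C = W.shape
    K = data.n_attributes
    eta = eta_prev.copy()
    flat_codes = data.codes.ravel()
    flat_s = data.switches.ravel().astype(float)
    for c in range(C):
        w = np.repeat(W[:, c], N_TASKS)
        N_k = np.bincount(flat_codes, weights=w, minlength=K)
        S_k = np.bincount(flat_codes, weights=w * flat_s, minlength=K)
        nonzero = N_k > 0
        p = np.clip(S_k[nonzero] / N_k[nonzero], _P_CLIP, 1 - _P_CLIP)
        eta[c, nonzero] = logit(p)
    return eta


def _em(
    data: LCLData,
    pi0: np.ndarray,
    eta0: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, np.ndarray, bool, bool]:
    """Run EM from one start; returns (pi, eta, ll, W, trace, converged, floored)."""
    pi, eta = pi0.copy(), eta0.copy()
    trace = []
    prev_ll = -np.inf
    converged = False
    floor_active = False
    W = np.full((data.n_respondents, len(pi)), 1.0 / len(pi))
    for _ in range(max_iter):
        ll_ic = _class_logliks(data, eta)
        log_num = ll_ic + np.log(pi)[None, :]
        log_den = logsumexp(log_num, axis=1, keepdims=True)
        ll = float(log_den.sum())
        trace.append(ll)
        W = np.exp(log_num - log_den)
        pi_new = W.mean(axis=0)
        if np.any(pi_new < _SHARE_FLOOR):
            floor_active = True
            pi_new = np.maximum(pi_new, _SHARE_FLOOR)
            pi_new = pi_new / pi_new.sum()
        eta = _m_step(data, W, eta)
        pi = pi_new
        if np.isfinite(prev_ll) and ll - prev_ll < tol * max(1.0, abs(ll)):
            converged = True
            break
        prev_ll = ll
    # final E-step so the posterior matches the returned parameters
    ll_ic = _class_logliks(data, eta)
    log_num = ll_ic + np.log(pi)[None, :]
    log_den = logsumexp(log_num, axis=1, keepdims=True)
    trace.append(float(log_den.sum()))
    W = np.exp(log_num - log_den)
    return pi, eta, trace[-1], W, np.asarray(trace), converged, floor_active


def _bic(ll: float, C: int, K: int, n: int) -> float:
    k = (C - 1) + C * K
    return k * np.log(n) - 2.0 * ll


def fit_lcl(
    data: LCLData,
    n_classes: int,
    n_starts: int = 20,
    rng: np.random.Generator | int | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    compute_se: bool = True,
) -> LCLFit:
    """Fit a C-class latent-class logit by multi-start EM.

    Each start draws per-respondent responsibilities from a symmetric
    Dirichlet(1) and takes one M-step to initialise the class parameters;
    the best converged solution over ``n_starts`` is returned with classes
    relabelled in increasing share order (so class 1 is the smallest).
    """
    if n_classes < 1:
        raise LCLError("n_classes must be >= 1")
    if n_classes > data.n_respondents:
        raise LCLError("more classes than respondents")
    rng = np.random.default_rng(rng)
    K = data.n_attributes
    n = data.n_respondents

    best = None
    log: list[str] = []
    traces: list[np.ndarray] = []
    any_converged = False
    for start in range(n_starts):
        W0 = rng.dirichlet(np.ones(n_classes), size=n)
        pi0 = W0.mean(axis=0)
        eta0 = _m_step(data, W0, np.zeros((n_classes, K)))
        pi, eta, ll, W, trace, conv, floored = _em(
            data, pi0, eta0, tol=tol, max_iter=max_iter
        )
        any_converged |= conv
        traces.append(trace)
        log.append(
            f"start {start}: loglik={ll:.6f} iters={len(trace) - 1} "
            f"converged={conv}" + (" share-floor-active" if floored else "")
        )
        if best is None or ll > best[2]:
            best = (pi, eta, ll, W, trace)
    if not any_converged:
        raise LCLError("no EM start converged:\n" + "\n".join(log))

    pi, eta, ll, W, trace = best
    order = np.argsort(pi)
    pi, eta, W = pi[order], eta[order], W[:, order]
    alphas = eta[:, 0]
    betas = eta[:, 1:] - eta[:, [0]]
    fit = LCLFit(
        n_classes=n_classes,
        class_shares=pi,
        alphas=alphas,
        betas=betas,
        log_likelihood=ll,
        bic=_bic(ll, n_classes, K, n),
        posterior=W,
        attribute_names=data.attribute_names,
        n_starts=n_starts,
        convergence_log=log,
        loglik_trace=traces,
    )
    if compute_se and n_classes >= 1:
        _attach_standard_errors(fit, data)
    return fit


def _pack(fit_pi: np.ndarray, alphas: np.ndarray, betas: np.ndarray) -> np.ndarray:
    C = len(fit_pi)
    share_logits = np.log(fit_pi[1:] / fit_pi[0]) if C > 1 else np.empty(0)
    return np.concatenate(
        [share_logits, alphas, betas.ravel()]
    )


def _unpack(params: np.ndarray, C: int, K: int):
    ncut = C - 1
    share_logits = params[:ncut]
    e = np.concatenate([[0.0], share_logits])
    pi = np.exp(e - logsumexp(e))
    alphas = params[ncut : ncut + C]
    betas = params[ncut + C :].reshape(C, K - 1)
    return pi, alphas, betas


def _attach_standard_errors(fit: LCLFit, data: LCLData) -> None:
    """Wald SEs from the numerically observed information of the mixture."""
    from statsmodels.tools.numdiff import approx_hess1

    C, K = fit.n_classes, data.n_attributes

    def negll(params):
        pi, alphas, betas = _unpack(params, C, K)
        return -lcl_loglik(pi, alphas, betas, data)

    x0 = _pack(fit.class_shares, fit.alphas, fit.betas)
    H = approx_hess1(x0, negll)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        fit.convergence_log.append("observed information singular; SEs omitted")
        return
    ncut = C - 1
    fit.share_se = se[:ncut]
    fit.alpha_se = se[ncut : ncut + C]
    fit.beta_se = se[ncut + C :].reshape(C, K - 1)


def select_n_classes(
    data: LCLData,
    candidate_range: Sequence[int] = range(2, 6),
    n_starts: int = 20,
    rng: np.random.Generator | int | None = None,
    **kwargs,
) -> tuple[LCLFit, pd.DataFrame]:
    """Fit every candidate class count and return the BIC-minimising fit.

    Ties break toward fewer classes.  The comparison table lists C, the
    parameter count, log-likelihood and BIC per candidate.
    """
    candidates = sorted(set(int(c) for c in candidate_range))
    if not candidates:
        raise LCLError("empty candidate range")
    rng = np.random.default_rng(rng)
    fits: dict[int, LCLFit] = {}
    rows = []
    for C in candidates:
        fit = fit_lcl(data, C, n_starts=n_starts, rng=rng, **kwargs)
        fits[C] = fit
        rows.append(
            {
                "n_classes": C,
                "n_params": (C - 1) + C * data.n_attributes,
                "log_likelihood": fit.log_likelihood,
                "bic": fit.bic,
            }
        )
    table = pd.DataFrame(rows)
    best_C = min(candidates, key=lambda C: (round(fits[C].bic, 9), C))
    return fits[best_C], table


def odds_ratios(fit: LCLFit, conf_level: float = 0.95) -> pd.DataFrame:
    """Per-class odds ratios vs the reference attribute with delta-method CIs.

    OR_ck = exp(beta_ck); the CI is computed on the log scale and
    exponentiated.  The reference attribute appears with OR fixed at 1.
    """
    from scipy.stats import norm

    z = norm.ppf(0.5 + conf_level / 2.0)
    rows = []
    for c in range(fit.n_classes):
        rows.append(
            {
                "class": c + 1,
                "attribute": fit.attribute_names[0],
                "odds_ratio": 1.0,
                "ci_low": 1.0,
                "ci_high": 1.0,
                "log_or": 0.0,
                "se": 0.0,
            }
        )
        for k, name in enumerate(fit.attribute_names[1:]):
            b = fit.betas[c, k]
            se = fit.beta_se[c, k] if fit.beta_se is not None else np.nan
            with np.errstate(over="ignore"):  # huge SEs give infinite CI ends
                rows.append(
                    {
                        "class": c + 1,
                        "attribute": name,
                        "odds_ratio": float(np.exp(b)),
                        "ci_low": float(np.exp(b - z * se)),
                        "ci_high": float(np.exp(b + z * se)),
                        "log_or": float(b),
                        "se": float(se),
                    }
                )
    return pd.DataFrame(rows)


def posterior_membership(fit: LCLFit, data: LCLData) -> np.ndarray:
    """Bayes posterior class-membership probabilities, rows summing to 1."""
    eta = fit.params_eta()
    ll_ic = _class_logliks(data, eta)
    log_num = ll_ic + np.log(fit.class_shares)[None, :]
    W = np.exp(log_num - logsumexp(log_num, axis=1, keepdims=True))
    return W


@dataclass(frozen=True)
class SwitchSummary:
    pct_tasks_switched: float
    pct_never_switched: float
    pct_always_switched: float
    per_class_switch_rates: tuple[float, ...]


def switch_summary(data: LCLData, W: np.ndarray | None = None) -> SwitchSummary:
    """Overall and modal-class-stratified switching statistics."""
    s = data.switches
    per_resp = s.sum(axis=1)
    pct_tasks = 100.0 * s.mean()
    pct_never = 100.0 * (per_resp == 0).mean()
    pct_always = 100.0 * (per_resp == N_TASKS).mean()
    rates: tuple[float, ...] = ()
    if W is not None:
        modal = W.argmax(axis=1)
        rates = tuple(
            float(100.0 * s[modal == c].mean()) if (modal == c).any() else float("nan")
            for c in range(W.shape[1])
        )
    return SwitchSummary(pct_tasks, pct_never, pct_always, rates)
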