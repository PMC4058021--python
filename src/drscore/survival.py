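"""Self-contained survival and categorical statistics.

Kaplan–Meier estimation, the two-group log-rank test, Cox
proportional-hazards fitting (Newton–Raphson, Efron or Breslow tie
handling) and Pearson chi-square association tests — the statistical
kernel every higher-level screening and scoring routine builds on.
All inputs are plain numpy arrays wrapped in small dataclasses with
eager validation; all p-values are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalData",
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "ContingencyResult",
    "NOT_REACHED",
    "km_estimate",
    "median_survival",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "chi_square_association",
]

#: Sentinel returned by :func:`median_survival` when the survival curve
#: never drops to 0.5 within follow-up.
NOT_REACHED = float("inf")


class ValidationError(ValueError):
    """Raised when survival inputs violate their invariants."""


@dataclass(frozen=True)
class SurvivalData:
    """Follow-up time (months) and event indicator for one endpoint.

    ``events[i] == 1`` means the event (death for OS, progression or
    death for EFS) was observed at ``times[i]``; 0 means the patient was
    censored at that time.
    """

    patient_ids: tuple
    times: np.ndarray
    events: np.ndarray
    endpoint_label: str = "OS"

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events)
        ids = tuple(self.patient_ids)
        if not (len(ids) == times.shape[0] == events.shape[0]):
            raise ValidationError("patient_ids, times and events must have equal length")
        if times.shape[0] < 1:
            raise ValidationError("survival data needs at least one record")
        if not np.all(times > 0):
            raise ValidationError("all follow-up times must be > 0")
        if not np.all(np.isin(events, (0, 1))):
            raise ValidationError("event indicators must be 0 (censored) or 1 (event)")
        if self.endpoint_label not in ("OS", "EFS"):
            raise ValidationError("endpoint_label must be 'OS' or 'EFS'")
        object.__setattr__(self, "patient_ids", ids)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events.astype(np.int8))

    def __len__(self) -> int:
        return self.times.shape[0]

    @classmethod
    def from_arrays(cls, times, events, endpoint_label="OS", patient_ids=None):
        times = np.asarray(times, dtype=float)
        if patient_ids is None:
            patient_ids = tuple(f"P{i}" for i in range(len(times)))
        return cls(tuple(patient_ids), times, np.asarray(events), endpoint_label)

    def subset(self, mask) -> "SurvivalData":
        mask = np.asarray(mask, dtype=bool)
        ids = tuple(pid for pid, m in zip(self.patient_ids, mask) if m)
        return SurvivalData(ids, self.times[mask], self.events[mask], self.endpoint_label)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate Ŝ(t) evaluated at the distinct event times."""

    distinct_event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk_counts: np.ndarray
    n_total: int

    def survival_at(self, t: float) -> float:
        """Ŝ(t): right-continuous step function, 1 before the first event."""
        idx = np.searchsorted(self.distinct_event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival_probs[idx - 1])


@dataclass(frozen=True)
class LogRankResult:
    z_statistic: float
    chi2: float
    p_value: float
    df: int = 1


@dataclass(frozen=True)
class CoxFit:
    covariate_names: tuple
    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    standard_errors: np.ndarray
    wald_p_values: np.ndarray
    log_partial_likelihood: float
    converged: bool
    ties_method: str
    n_iter: int = 0
    message: str = ""


@dataclass(frozen=True)
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# Kaplan–Meier


def km_estimate(survival: SurvivalData) -> KMCurve:
    """Product-limit estimator of the survival function.

    Patients censored exactly at an event time are still counted in the
    risk set at that time (they leave the risk set *after* it).
    """
    times, events = survival.times, survival.events
    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]
    event_times = np.unique(t_sorted[e_sorted == 1])
    if event_times.size == 0:
        return KMCurve(np.empty(0), np.empty(0), np.empty(0, dtype=int), len(survival))
    # at risk at t: everyone with follow-up >= t
    n_at_risk = np.array([(times >= t).sum() for t in event_times])
    n_deaths = np.array([((times == t) & (events == 1)).sum() for t in event_times])
    surv = np.cumprod(1.0 - n_deaths / n_at_risk)
    return KMCurve(event_times, surv, n_at_risk, len(survival))


def median_survival(curve: KMCurve) -> float:
    """Smallest t with Ŝ(t) ≤ 0.5, or ``NOT_REACHED`` (inf)."""
    below = np.nonzero(curve.survival_probs <= 0.5)[0]
    if below.size == 0:
        return NOT_REACHED
    return float(curve.distinct_event_times[below[0]])


# ---------------------------------------------------------------------------
# Log-rank test


def _logrank_oev(times, events, group):
    """(O − E, V) for group-1 with the hypergeometric variance."""
    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        dying = (times == t) & (events == 1)
        d = dying.sum()
        d1 = (dying & group).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e, var


def logrank_test(survival: SurvivalData, group_labels: Sequence[int]) -> LogRankResult:
    """Two-group log-rank test; z is signed for group 1 (O₁ > E₁ ⇒ z > 0)."""
    group = np.asarray(group_labels).astype(bool)
    if group.shape[0] != len(survival):
        raise ValidationError("group_labels length mismatch")
    if group.all() or (~group).all():
        raise ValidationError("both groups must be non-empty")
    if survival.events.sum() == 0:
        raise ValidationError("log-rank statistic undefined without any events")
    o_minus_e, var = _logrank_oev(survival.times, survival.events, group)
    if var <= 0:
        return LogRankResult(0.0, 0.0, 1.0)
    z = o_minus_e / math.sqrt(var)
    chi2 = z * z
    p = float(stats.chi2.sf(chi2, 1))
    return LogRankResult(float(z), float(chi2), max(p, np.finfo(float).tiny))


# ---------------------------------------------------------------------------
# Cox proportional hazards


def _cox_loglik(beta, times, events, X, ties):
    """Log partial likelihood with gradient and Hessian, fully vectorized.

    Patients are sorted by descending time so risk-set aggregates
    S0 = Σ w, S1 = Σ w·x, S2 = Σ w·x·xᵀ are prefix sums; tied-death
    blocks are reduced with ``np.add.reduceat`` and Efron's correction
    subtracts the fraction ℓ/d of the tie-block aggregates for every
    death slot ℓ (Breslow is the same path with the fraction zeroed).
    """
    n, k = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # overflow guard; partial likelihood is shift-invariant
    w = np.exp(eta)
    order = np.argsort(-times, kind="stable")  # descending time
    t_s, e_s, X_s, w_s, eta_s = times[order], events[order], X[order], w[order], eta[order]

    cw = np.cumsum(w_s)
    wX = w_s[:, None] * X_s
    cwx = np.cumsum(wX, axis=0)
    wXX = wX[:, :, None] * X_s[:, None, :]
    cwxx = np.cumsum(wXX, axis=0)

    # tie blocks of equal time
    starts = np.flatnonzero(np.r_[True, t_s[1:] != t_s[:-1]])
    ends = np.r_[starts[1:], n] - 1  # inclusive last index per block
    em = (e_s == 1).astype(float)
    d_b = np.add.reduceat(em, starts)  # deaths per block
    has_d = d_b > 0
    if not has_d.any():
        return 0.0, np.zeros(k), np.zeros((k, k))
    s0 = cw[ends][has_d]
    s1 = cwx[ends][has_d]
    s2 = cwxx[ends][has_d]
    td0 = np.add.reduceat(em * w_s, starts)[has_d]
    td1 = np.add.reduceat(em[:, None] * wX, starts, axis=0)[has_d]
    td2 = np.add.reduceat(em[:, None, None] * wXX, starts, axis=0)[has_d]
    xd_sum = np.add.reduceat(em[:, None] * X_s, starts, axis=0)[has_d]
    eta_d = np.add.reduceat(em * eta_s, starts)[has_d]
    d = d_b[has_d].astype(int)

    # one row per death slot: block index rep, within-block rank ell
    rep = np.repeat(np.arange(d.size), d)
    ell = np.arange(d.sum()) - np.repeat(np.cumsum(d) - d, d)
    frac = np.zeros(d.sum()) if ties == "breslow" else ell / d[rep]
    a0 = s0[rep] - frac * td0[rep]
    a1 = s1[rep] - frac[:, None] * td1[rep]
    a2 = s2[rep] - frac[:, None, None] * td2[rep]

    loglik = float(eta_d.sum() - np.log(a0).sum())
    grad = xd_sum.sum(axis=0) - (a1 / a0[:, None]).sum(axis=0)
    r1 = a1 / a0[:, None]
    hess = -(a2 / a0[:, None, None]).sum(axis=0) + np.einsum("ij,il->jl", r1, r1)
    return loglik, grad, hess


def cox_fit(
    survival: SurvivalData,
    covariates,
    covariate_names=None,
    ties_method: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Maximize the Cox log partial likelihood by Newton–Raphson.

    Step-halving guards each update; convergence is declared on the
    max-norm of the gradient.  Monotone-likelihood (separation) inputs
    are reported with ``converged=False`` rather than diverging silently.
    """
    if ties_method not in ("efron", "breslow"):
        raise ValidationError(f"unknown ties_method {ties_method!r}")
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != len(survival):
        X = X.T
    if X.shape[0] != len(survival):
        raise ValidationError("covariate matrix does not align with survival data")
    n, k = X.shape
    if k < 1:
        raise ValidationError("at least one covariate required")
    if n < k + 1:
        raise ValidationError("need more patients than covariates")
    col_sd = X.std(axis=0)
    if np.any(col_sd == 0):
        bad = [i for i, s in enumerate(col_sd) if s == 0]
        raise ValidationError(f"constant covariate column(s) {bad}: model not identifiable")
    if covariate_names is None:
        covariate_names = tuple(f"x{i}" for i in range(k))
    times, events = survival.times, survival.events
    if events.sum() == 0:
        raise ValidationError("cannot fit Cox model without any events")

    # standardize for numerical stability; back-transform at the end
    mu, sd = X.mean(axis=0), col_sd
    Xs = (X - mu) / sd

    beta = np.zeros(k)
    loglik, grad, hess = _cox_loglik(beta, times, events, Xs, ties_method)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        # step-halving on the partial likelihood
        new_beta = beta + step
        new = _cox_loglik(new_beta, times, events, Xs, ties_method)
        halvings = 0
        while new[0] < loglik - 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new = _cox_loglik(new_beta, times, events, Xs, ties_method)
            halvings += 1
        beta = new_beta
        loglik, grad, hess = new
        if np.max(np.abs(beta)) > 50:
            message = "monotone partial likelihood (separation): coefficient diverging"
            break
    else:
        if np.max(np.abs(grad)) < tol:
            converged = True
        else:
            message = "maximum iterations reached"
    if converged and np.max(np.abs(grad)) >= tol:
        converged = False
    # monotone likelihood: the gradient also vanishes as β runs away, so a
    # huge standardized coefficient at "convergence" still means separation
    if np.max(np.abs(beta)) > 10:
        converged = False
        message = message or "monotone partial likelihood (separation): estimate unbounded"

    info = -hess
    try:
        cov = np.linalg.inv(info)
        se_s = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_s = np.full(k, np.nan)
    # back to original covariate scale
    beta_orig = beta / sd
    se_orig = se_s / sd
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta_orig / se_orig
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return CoxFit(
        covariate_names=tuple(covariate_names),
        coefficients=beta_orig,
        hazard_ratios=np.exp(beta_orig),
        standard_errors=se_orig,
        wald_p_values=p,
        log_partial_likelihood=float(loglik),
        converged=converged,
        ties_method=ties_method,
        n_iter=it,
        message=message,
    )


def cox_log_partial_likelihood(survival, covariates, beta, ties_method="efron"):
    """Log partial likelihood at an arbitrary β (brute-force grid oracle hook)."""
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != len(survival):
        X = X.T
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    ll, _, _ = _cox_loglik(beta, survival.times, survival.events, X, ties_method)
    return float(ll)


def cox_score_test(survival: SurvivalData, covariate) -> LogRankResult:
    """Score (Rao) test of β = 0 for a single covariate, Breslow form.

    For a binary covariate without tied event times this reproduces the
    log-rank chi-square exactly — used as an internal consistency oracle.
    """
    x = np.asarray(covariate, dtype=float).reshape(-1, 1)
    _, grad, hess = _cox_loglik(np.zeros(1), survival.times, survival.events, x, "breslow")
    info = float(-hess[0, 0])
    if info <= 0:
        return LogRankResult(0.0, 0.0, 1.0)
    z = float(grad[0]) / math.sqrt(info)
    chi2 = z * z
    return LogRankResult(z, chi2, float(max(stats.chi2.sf(chi2, 1), np.finfo(float).tiny)))


# ---------------------------------------------------------------------------
# Chi-square association


def chi_square_association(observed) -> ContingencyResult:
    """Pearson chi-square test of independence, no continuity correction."""
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValidationError("need an r×c table with r ≥ 2 and c ≥ 2")
    if np.any(obs < 0):
        raise ValidationError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValidationError("zero row or column margin: drop the empty category first")
    expected = np.outer(row, col) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(max(stats.chi2.sf(chi2, df), np.finfo(float).tiny))
    return ContingencyResult(obs.astype(int), expected, chi2, df, p)
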