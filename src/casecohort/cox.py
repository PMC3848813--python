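"""Weighted Cox pseudolikelihood for case-cohort data.

The log pseudolikelihood is

    l(beta) = sum_events [ beta x_i - log sum_{j in R(t_i)} w_j e^{beta x_j} ]

with scheme-specific risk sets R and weights w (see :mod:`casecohort.design`)
and Breslow handling of tied event times.  Newton-Raphson with step-halving
maximises it.  The model-based ("naive") covariance is the inverse observed
information; because the pseudolikelihood score terms are not martingale
increments under subcohort sampling, inference uses instead the robust
sandwich estimate built from per-subject score residuals (the
infinitesimal-jackknife / DFBETA estimator).

Absolute risks come from a weighted Breslow estimator of the cumulative
baseline hazard: for the Prentice and Self & Prentice schemes the subcohort
denominator is rescaled by 1/alpha to emulate the full cohort, while the
Barlow denominator already mimics full-cohort proportions and needs no
rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .design import CaseCohortDesign, SCHEMES, _check_scheme


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class CoxFit:
    """A converged weighted Cox fit."""

    betas: np.ndarray
    naive_covariance: np.ndarray
    robust_covariance: np.ndarray
    scheme: str
    alpha: float
    covariate_names: tuple[str, ...]
    x_mean: np.ndarray
    loglik: float
    n_iter: int
    final_grad_norm: float

    @property
    def se_naive(self) -> np.ndarray:
        return np.sqrt(np.diag(self.naive_covariance))

    @property
    def se_robust(self) -> np.ndarray:
        return np.sqrt(np.diag(self.robust_covariance))

    def linear_predictor(self, x: np.ndarray) -> np.ndarray:
        """Centred linear predictor (x - x_mean) @ beta for rows of x."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return (x - self.x_mean) @ self.betas

    def export(self, path) -> None:
        """Write a structured text summary (name, beta, SEs, metadata)."""
        import io

        buf = io.StringIO()
        buf.write(f"# scheme: {self.scheme}\n# alpha: {self.alpha}\n")
        buf.write(f"# iterations: {self.n_iter}\n# loglik: {self.loglik!r}\n")
        buf.write("covariate,beta,se_naive,se_robust\n")
        for name, b, sn, sr in zip(self.covariate_names, self.betas, self.se_naive, self.se_robust):
            buf.write(f"{name},{b!r},{sn!r},{sr!r}\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


@dataclass(frozen=True)
class BaselineHazard:
    """Step-function cumulative baseline hazard (right-continuous)."""

    times: np.ndarray
    cumhaz: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        h = np.asarray(self.cumhaz, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("baseline times must be strictly increasing")
        if np.any(np.diff(h) < 0) or (len(h) and h[0] < 0):
            raise ValueError("cumulative hazard must be non-decreasing and >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cumhaz", h)

    def cumulative_hazard(self, t) -> np.ndarray:
        """Lambda_0(t): 0 before the first event time, step at each event."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate([[0.0], self.cumhaz])
        return padded[idx]

    def survival(self, t) -> np.ndarray:
        """Baseline survival S_0(t) = exp(-Lambda_0(t))."""
        return np.exp(-self.cumulative_hazard(t))

    def export(self, path, sep: str = ",") -> None:
        import pandas as pd

        pd.DataFrame({"time": self.times, "cumhaz": self.cumhaz}).to_csv(
            path, sep=sep, index=False, float_format="%.17g"
        )


# ---------------------------------------------------------------------------
# internal analysis arrays

@dataclass
class _Arrays:
    """Case-cohort-set arrays prepared for the pseudolikelihood."""

    x: np.ndarray          # (m, p) centred covariates, members of the set
    exit: np.ndarray       # (m,)
    event: np.ndarray      # (m,) 0/1
    sub: np.ndarray        # (m,) bool, subcohort membership
    alpha: float
    x_mean: np.ndarray
    # sorted views
    sub_exit_sorted: np.ndarray   # subcohort exit times ascending
    sub_order: np.ndarray         # indices of subcohort members in that order
    t_event: np.ndarray           # distinct event times ascending
    d: np.ndarray                 # tied-event counts per distinct time
    event_group: np.ndarray       # for each event row, index into t_event
    event_rows: np.ndarray        # member indices with event == 1
    sub_pos: np.ndarray           # searchsorted position of each t_event in sub_exit_sorted


def _prepare(design: CaseCohortDesign, covariate_names: Sequence[str] | None) -> _Arrays:
    cohort = design.cohort
    if covariate_names is None:
        covariate_names = cohort.covariate_names
    members = design.member_indices()
    x = cohort.covariate_matrix(covariate_names)[members]
    exit_t = cohort.exit[members]
    event = cohort.event[members]
    sub = design.in_subcohort[members]
    if event.sum() < 1:
        raise ValueError("no events in the case-cohort set")
    x_mean = x.mean(axis=0)
    xc = x - x_mean
    if np.any(xc.std(axis=0) == 0):
        degenerate = [covariate_names[j] for j in np.flatnonzero(xc.std(axis=0) == 0)]
        raise ValueError(f"degenerate covariate(s) on the case-cohort set: {degenerate}")
    sub_order = np.flatnonzero(sub)
    sub_order = sub_order[np.argsort(exit_t[sub_order], kind="stable")]
    sub_exit_sorted = exit_t[sub_order]
    event_rows = np.flatnonzero(event == 1)
    t_event, event_group, d = np.unique(
        exit_t[event_rows], return_inverse=True, return_counts=True
    )
    sub_pos = np.searchsorted(sub_exit_sorted, t_event, side="left")
    return _Arrays(
        x=xc,
        exit=exit_t,
        event=event,
        sub=sub,
        alpha=design.alpha,
        x_mean=x_mean,
        sub_exit_sorted=sub_exit_sorted,
        sub_order=sub_order,
        t_event=t_event,
        d=d,
        event_group=event_group,
        event_rows=event_rows,
        sub_pos=sub_pos,
    )


def _denominators_allow_zero(a: "_Arrays", scheme: str, eta: np.ndarray):
    return _denominators(a, scheme, eta, order=1, check=False)


def _denominators(a: _Arrays, scheme: str, eta: np.ndarray, order: int = 2, check: bool = True):
    """Per-distinct-event-time weighted sums S0, S1, S2 of w e^eta (x, xx')."""
    r = np.exp(eta)
    k = len(a.t_event)
    p = a.x.shape[1]
    # suffix sums over subcohort members sorted by exit: at risk at t_k means
    # exit >= t_k, i.e. positions sub_pos[k] ... end
    rs = r[a.sub_order]
    xs = a.x[a.sub_order]
    suff0 = np.concatenate([np.cumsum(rs[::-1])[::-1], [0.0]])
    S0 = suff0[a.sub_pos]
    rx = rs[:, None] * xs
    suff1 = np.vstack([np.cumsum(rx[::-1], axis=0)[::-1], np.zeros((1, p))])
    S1 = suff1[a.sub_pos]
    if order >= 2:
        rxx = rx[:, :, None] * xs[:, None, :]
        suff2 = np.concatenate(
            [np.cumsum(rxx[::-1], axis=0)[::-1], np.zeros((1, p, p))], axis=0
        )
        S2 = suff2[a.sub_pos]
    else:
        S2 = None

    # event-row adjustments grouped by distinct event time
    ev = a.event_rows
    ev_sub = a.sub[ev]
    rev = r[ev]
    xev = a.x[ev]

    def group_sum(vals, mask):
        out0 = np.zeros(k)
        np.add.at(out0, a.event_group[mask], vals[mask])
        return out0

    def group_sum_vec(vals, mask):
        out = np.zeros((k,) + vals.shape[1:])
        np.add.at(out, a.event_group[mask], vals[mask])
        return out

    if scheme == "self_prentice":
        pass  # subcohort-only denominators
    elif scheme == "prentice":
        ns = ~ev_sub
        S0 = S0 + group_sum(rev, ns)
        S1 = S1 + group_sum_vec(rev[:, None] * xev, ns)
        if order >= 2:
            S2 = S2 + group_sum_vec(rev[:, None, None] * xev[:, :, None] * xev[:, None, :], ns)
    else:  # barlow
        w = 1.0 / a.alpha
        ns = ~ev_sub
        s = ev_sub
        S0 = w * S0 + group_sum(rev, ns) + (1.0 - w) * group_sum(rev, s)
        S1 = w * S1 + group_sum_vec(rev[:, None] * xev, ns) + (1.0 - w) * group_sum_vec(
            rev[:, None] * xev, s
        )
        if order >= 2:
            xx = rev[:, None, None] * xev[:, :, None] * xev[:, None, :]
            S2 = w * S2 + group_sum_vec(xx, ns) + (1.0 - w) * group_sum_vec(xx, s)
    if check and np.any(S0 <= 0):
        bad = a.t_event[np.flatnonzero(S0 <= 0)[0]]
        raise ZeroDivisionError(f"empty weighted risk set at event time t={bad}")
    return S0, S1, S2


def _loglik_grad_hess(a: _Arrays, scheme: str, beta: np.ndarray):
    eta = a.x @ beta
    S0, S1, S2 = _denominators(a, scheme, eta)
    ll = float(eta[a.event_rows].sum() - np.sum(a.d * np.log(S0)))
    xbar = S1 / S0[:, None]
    grad = a.x[a.event_rows].sum(axis=0) - (a.d[:, None] * xbar).sum(axis=0)
    v = S2 / S0[:, None, None] - xbar[:, :, None] * xbar[:, None, :]
    hess = -(a.d[:, None, None] * v).sum(axis=0)
    return ll, grad, hess


def pseudo_loglik(
    design: CaseCohortDesign,
    beta: Sequence[float],
    scheme: str = "prentice",
    covariate_names: Sequence[str] | None = None,
) -> float:
    """Value of the log pseudolikelihood at a given beta (raw covariate scale).

    Covariates are centred internally, which leaves the partial-likelihood
    value unchanged (the centring constant cancels between numerator and
    denominator of every risk set).
    """
    _check_scheme(scheme)
    a = _prepare(design, covariate_names)
    beta = np.asarray(beta, dtype=float)
    ll, _, _ = _loglik_grad_hess(a, scheme, beta)
    return ll


def fit_weighted_cox(
    design: CaseCohortDesign,
    covariate_names: Sequence[str] | None = None,
    scheme: str = "prentice",
    start: Sequence[float] | None = None,
    tol: float = 1e-9,
    grad_tol: float = 1e-6,
    max_iter: int = 100,
) -> CoxFit:
    """Maximise the case-cohort pseudolikelihood by Newton-Raphson.

    Parameters
    ----------
    design : the drawn case-cohort design (alpha = 1 for a full cohort).
    covariate_names : subset of cohort covariates to model (default all).
    scheme : ``prentice`` (default), ``self_prentice`` or ``barlow``.
    start : initial beta (default zero).
    tol : relative change in log pseudolikelihood declaring convergence.
    grad_tol : max-norm gradient threshold that must also hold.
    max_iter : Newton iteration cap.

    Ties are handled with the Breslow approximation.  Diverging
    coefficients (monotone pseudolikelihood / separation) raise
    :class:`ConvergenceError`.
    """
    _check_scheme(scheme)
    a = _prepare(design, covariate_names)
    if covariate_names is None:
        covariate_names = design.cohort.covariate_names
    p = a.x.shape[1]
    beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    ll, grad, hess = _loglik_grad_hess(a, scheme, beta)
    trace = [(0, ll, float(np.abs(grad).max()))]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}", trace) from exc
        new_beta = beta + step
        new_ll, new_grad, new_hess = _loglik_grad_hess(a, scheme, new_beta)
        halvings = 0
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            halvings += 1
            if halvings > 30:
                raise ConvergenceError("step-halving failed to improve the pseudolikelihood", trace)
            step = step / 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _loglik_grad_hess(a, scheme, new_beta)
        beta, grad, hess = new_beta, new_grad, new_hess
        rel = abs(new_ll - ll) / (abs(ll) + 1e-300)
        ll = new_ll
        trace.append((n_iter, ll, float(np.abs(grad).max())))
        if np.abs(beta).max() > 50.0:
            raise ConvergenceError(
                "coefficients diverging (|beta| > 50): monotone pseudolikelihood "
                "suggests separation in the covariates",
                trace,
            )
        if rel < tol and np.abs(grad).max() < grad_tol:
            break
    else:
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations (|grad|={np.abs(grad).max():.2e})",
            trace,
        )
    info_inv = np.linalg.inv(-hess)
    fit = CoxFit(
        betas=beta,
        naive_covariance=info_inv,
        robust_covariance=np.full((p, p), np.nan),
        scheme=scheme,
        alpha=design.alpha,
        covariate_names=tuple(covariate_names),
        x_mean=a.x_mean,
        loglik=ll,
        n_iter=n_iter,
        final_grad_norm=float(np.abs(grad).max()),
    )
    robust = _robust_covariance(a, scheme, beta, info_inv)
    object.__setattr__(fit, "robust_covariance", robust)
    return fit


def _robust_covariance(a: _Arrays, scheme: str, beta: np.ndarray, info_inv: np.ndarray) -> np.ndarray:
    """Sandwich I^-1 (sum_i U_i U_i') I^-1 from per-subject score residuals."""
    eta = a.x @ beta
    r = np.exp(eta)
    S0, S1, _ = _denominators(a, scheme, eta, order=1)
    xbar = S1 / S0[:, None]
    dk = a.d / S0
    # cumulative (over event times <= t) of d/S0 and d*xbar/S0
    A = np.concatenate([[0.0], np.cumsum(dk)])
    B = np.vstack([np.zeros(a.x.shape[1]), np.cumsum(dk[:, None] * xbar, axis=0)])
    m = len(a.exit)
    U = np.zeros((m, a.x.shape[1]))
    # event (numerator) part
    ev = a.event_rows
    U[ev] += a.x[ev] - xbar[a.event_group]
    # denominator part: subcohort members are at risk through their exit
    kpos = np.searchsorted(a.t_event, a.exit, side="right")  # events with t_k <= exit_i
    base_w = 1.0 if scheme in ("prentice", "self_prentice") else 1.0 / a.alpha
    subm = a.sub
    U[subm] -= base_w * r[subm, None] * (A[kpos[subm], None] * a.x[subm] - B[kpos[subm]])
    if scheme == "barlow":
        # a subcohort case carries weight 1, not 1/alpha, at its own event time
        sub_ev = ev[a.sub[ev]]
        g = a.event_group[a.sub[ev]]
        corr = (1.0 - 1.0 / a.alpha) * r[sub_ev, None] * dk[g, None] * (a.x[sub_ev] - xbar[g])
        U[sub_ev] -= corr
    if scheme in ("prentice", "barlow"):
        # non-subcohort case: in the denominator only at its own event time
        ns_ev = ev[~a.sub[ev]]
        g = a.event_group[~a.sub[ev]]
        U[ns_ev] -= r[ns_ev, None] * dk[g, None] * (a.x[ns_ev] - xbar[g])
    meat = U.T @ U
    return info_inv @ meat @ info_inv


def robust_variance(fit: CoxFit, design: CaseCohortDesign) -> np.ndarray:
    """Recompute the robust sandwich covariance of a converged fit.

    Aggregates each subject's score contributions across every risk set it
    enters (with its scheme weights) into a score residual, and returns
    ``I^-1 (sum_i U_i U_i') I^-1``.
    """
    a = _prepare(design, fit.covariate_names)
    _, _, hess = _loglik_grad_hess(a, fit.scheme, fit.betas)
    try:
        info_inv = np.linalg.inv(-hess)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular information matrix: {exc}") from exc
    return _robust_covariance(a, fit.scheme, fit.betas, info_inv)


def breslow_baseline(
    fit: CoxFit,
    design: CaseCohortDesign,
    scheme: str | None = None,
    include_nonsub_case_at_event: bool = False,
) -> BaselineHazard:
    """Weighted Breslow estimate of the cumulative baseline hazard.

    For the Prentice and Self & Prentice schemes the denominator is the
    subcohort sum rescaled by 1/alpha,

        D(t_k) = (1/alpha) * sum_{subcohort j at risk} e^{beta x_j},

    which estimates the full-cohort denominator; by default a non-subcohort
    case is excluded from the denominator even at its own event time.
    ``include_nonsub_case_at_event`` adds tied non-subcohort cases with
    weight 1 (not rescaled) at their own event times, which keeps every
    denominator strictly positive even when no subcohort member remains at
    risk at a late event — useful at very small sampling fractions.  For
    Barlow the scheme's own weighted denominator is used with no further
    rescaling.  The estimator is on the centred covariate scale of the
    fit; use :func:`predict_absolute_risk`.
    """
    scheme = _check_scheme(scheme or fit.scheme)
    a = _prepare(design, fit.covariate_names)
    eta = a.x @ fit.betas
    if scheme == "barlow":
        D, _, _ = _denominators(a, "barlow", eta, order=1)
    else:
        S0_sub, _, _ = _denominators_allow_zero(a, "self_prentice", eta)
        D = S0_sub / a.alpha
        if include_nonsub_case_at_event:
            S0_pre, _, _ = _denominators_allow_zero(a, "prentice", eta)
            D = D + (S0_pre - S0_sub)
    if np.any(D <= 0):
        bad = a.t_event[np.flatnonzero(D <= 0)[0]]
        raise ZeroDivisionError(f"zero weighted denominator at event time t={bad}")
    return BaselineHazard(times=a.t_event, cumhaz=np.cumsum(a.d / D))


def predict_absolute_risk(
    fit: CoxFit, baseline: BaselineHazard, x: np.ndarray, t
) -> np.ndarray:
    """Absolute event risk by horizon t: 1 - S_0(t)^exp(beta x).

    ``x`` is one covariate vector or an (n, p) matrix on the raw scale; the
    centring used during fitting is applied automatically (the baseline must
    come from the same fit).  Returns risks in [0, 1].
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("horizon t must be >= 0")
    lp = fit.linear_predictor(x)
    ch = baseline.cumulative_hazard(t)
    risk = -np.expm1(-np.multiply.outer(ch, np.exp(lp)))
    return np.squeeze(risk)
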