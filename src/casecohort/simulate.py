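"""Synthetic covariate generation and Weibull outcome simulation.

Event times follow a Weibull proportional-hazards model with cumulative
hazard ``H(t | x) = (lambda * t)**gamma * exp(beta @ x)`` — the shape/rate
parametrisation in which ``lambda`` (per year) is the reciprocal of the
Weibull scale, so halving the rate parameter scales every cumulative hazard
by ``2**-gamma``.  Inversion sampling gives
``T = (-log U * exp(-beta @ x))**(1/gamma) / lambda`` for U ~ Uniform(0, 1).
Staggered entry over a calendar window combined with an
administrative study end induces random censoring of the follow-up time.

Covariates are drawn from marginal moments (continuous: mean/sd, binary:
prevalence) through a Gaussian copula, so an optional correlation matrix can
couple them; the default is independence.  ``calibrate_weibull`` solves for
(lambda, gamma) reproducing target marginal cumulative incidences at two
horizons, which is how a generating model is pinned down when only published
incidences — not the fitted Weibull parameters — are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .cohort import Cohort


class CalibrationError(RuntimeError):
    """Raised when no (lambda, gamma) matches the incidence targets."""


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal covariate distributions, optionally coupled by a copula.

    Parameters
    ----------
    names : covariate labels, in model order.
    kinds : per covariate, ``"continuous"`` or ``"binary"``.
    means : mean for continuous covariates, prevalence for binary ones.
    sds : standard deviation for continuous covariates; ignored (set 0)
        for binary ones.
    correlation : latent Gaussian correlation matrix (unit diagonal,
        symmetric positive definite); ``None`` means independence.
    """

    names: tuple[str, ...]
    kinds: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = len(self.names)
        if not (len(self.kinds) == len(self.means) == len(self.sds) == p):
            raise ValueError("names/kinds/means/sds must have equal length")
        for kind, mean, sd in zip(self.kinds, self.means, self.sds):
            if kind == "continuous":
                if sd <= 0:
                    raise ValueError("continuous covariate needs sd > 0")
            elif kind == "binary":
                if not 0 < mean < 1:
                    raise ValueError("binary prevalence must lie in (0, 1)")
            else:
                raise ValueError(f"unknown covariate kind '{kind}'")
        if self.correlation is not None:
            R = np.asarray(self.correlation, dtype=float)
            if R.shape != (p, p):
                raise ValueError("correlation matrix has wrong shape")
            if not np.allclose(R, R.T):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(R), 1.0):
                raise ValueError("correlation matrix must have unit diagonal")
            if np.linalg.eigvalsh(R)[0] <= 0:
                raise ValueError("correlation matrix must be positive definite")
            object.__setattr__(self, "correlation", R)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "kinds", tuple(self.kinds))
        object.__setattr__(self, "means", tuple(float(m) for m in self.means))
        object.__setattr__(self, "sds", tuple(float(s) for s in self.sds))

    @property
    def n_covariates(self) -> int:
        return len(self.names)

    def to_dict(self) -> dict:
        d = {
            "names": list(self.names),
            "kinds": list(self.kinds),
            "means": list(self.means),
            "sds": list(self.sds),
        }
        if self.correlation is not None:
            d["correlation"] = self.correlation.tolist()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CovariateSpec":
        corr = d.get("correlation")
        return cls(
            names=tuple(d["names"]),
            kinds=tuple(d["kinds"]),
            means=tuple(d["means"]),
            sds=tuple(d["sds"]),
            correlation=None if corr is None else np.asarray(corr, dtype=float),
        )


@dataclass(frozen=True)
class WeibullModel:
    """Weibull proportional-hazards generating model.

    ``gamma`` is the Weibull shape, ``rate`` the Weibull rate parameter
    lambda (per year; the reciprocal of the scale) and ``betas`` the true
    log hazard ratios per unit of each covariate, so that
    ``H(t | x) = (rate * t)**gamma * exp(betas @ x)``.
    """

    gamma: float
    rate: float
    betas: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        object.__setattr__(self, "betas", tuple(float(b) for b in self.betas))

    def halved_rate(self) -> "WeibullModel":
        """Same model with the rate parameter halved (lower incidence).

        Halving the rate multiplies every cumulative hazard by 2**-gamma.
        """
        return WeibullModel(gamma=self.gamma, rate=self.rate / 2.0, betas=self.betas)

    def cumulative_hazard(self, t, linear_predictor) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.rate * t) ** self.gamma * np.exp(np.asarray(linear_predictor, dtype=float))

    def to_dict(self) -> dict:
        return {"gamma": self.gamma, "rate": self.rate, "betas": list(self.betas)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "WeibullModel":
        return cls(gamma=float(d["gamma"]), rate=float(d["rate"]), betas=tuple(d["betas"]))


def betas_per_unit(per_sd_log_hrs: Sequence[float], spec: CovariateSpec) -> tuple[float, ...]:
    """Convert published log hazard ratios to the raw covariate scale.

    Continuous covariates are typically reported per standard deviation;
    divide by the SD to get the per-unit coefficient.  Binary covariates are
    reported per category and pass through unchanged.
    """
    out = []
    for b, kind, sd in zip(per_sd_log_hrs, spec.kinds, spec.sds):
        out.append(float(b) / sd if kind == "continuous" else float(b))
    return tuple(out)


def generate_covariates(n: int, spec: CovariateSpec, seed: int) -> np.ndarray:
    """Draw an (n, p) covariate matrix from a spec, deterministically by seed.

    A Gaussian copula realises the correlation structure: latent standard
    normals are transformed to the marginal scale, binary covariates by
    thresholding at the prevalence quantile.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p = spec.n_covariates
    if spec.correlation is None:
        z = rng.standard_normal((n, p))
    else:
        chol = np.linalg.cholesky(spec.correlation)
        z = rng.standard_normal((n, p)) @ chol.T
    x = np.empty((n, p))
    for j, (kind, mean, sd) in enumerate(zip(spec.kinds, spec.means, spec.sds)):
        if kind == "continuous":
            x[:, j] = mean + sd * z[:, j]
        else:
            # P(Z > z_{1-prev}) = prevalence
            x[:, j] = (z[:, j] > stats.norm.ppf(1.0 - mean)).astype(float)
    return x


def marginal_incidence(
    rate: float, gamma: float, t: float, linear_predictor: np.ndarray
) -> float:
    """Marginal cumulative incidence E_x[1 - exp(-(rate * t)**gamma * e^lp)]."""
    return float(np.mean(-np.expm1(-((rate * t) ** gamma) * np.exp(linear_predictor))))


def calibrate_weibull(
    spec: CovariateSpec,
    betas: Sequence[float],
    inc10: float,
    inc25: float,
    t_low: float = 10.0,
    t_high: float = 25.0,
    n_mc: int = 200_000,
    seed: int = 2_013_113,
    tol: float = 1e-6,
) -> WeibullModel:
    """Solve for (rate, gamma) matching two marginal cumulative incidences.

    The expectation over the covariate distribution uses a large fixed Monte
    Carlo draw of the linear predictor (``n_mc`` subjects, ``seed``ed so the
    calibration is reproducible).  Nested root finding: for each trial gamma
    the rate solving the ``t_low`` target is found by bisection in log-rate,
    then gamma is adjusted until the ``t_high`` target is met.

    ``betas`` are log hazard ratios on the raw covariate scale (see
    :func:`betas_per_unit`).
    """
    if not 0.0 < inc10 < inc25 < 1.0:
        raise ValueError("need 0 < inc10 < inc25 < 1")
    betas = np.asarray(betas, dtype=float)
    if len(betas) != spec.n_covariates:
        raise ValueError("betas length must match the covariate spec")
    x = generate_covariates(n_mc, spec, seed=seed)
    lp = x @ betas
    # Centre the linear predictor for conditioning; fold the offset back into
    # the rate at the end (rate * e^lp is invariant).
    offset = float(np.mean(lp))
    lp_c = lp - offset

    def rate_for(gamma: float) -> float:
        def f(log_rate: float) -> float:
            return marginal_incidence(np.exp(log_rate), gamma, t_low, lp_c) - inc10

        # bounds wide enough that (rate*t)**gamma spans the unit interval
        # even for extreme shapes
        lo, hi = -60.0 / gamma - 10.0, 20.0 / gamma + 10.0
        if f(lo) > 0 or f(hi) < 0:
            raise CalibrationError(
                f"no rate in bounds for gamma={gamma:.4f}: "
                f"f({lo})={f(lo):.3e}, f({hi})={f(hi):.3e}"
            )
        return float(np.exp(optimize.brentq(f, lo, hi, xtol=1e-13, rtol=1e-14)))

    def g(gamma: float) -> float:
        r = rate_for(gamma)
        return marginal_incidence(r, gamma, t_high, lp_c) - inc25

    glo, ghi = 0.05, 10.0
    try:
        if g(glo) * g(ghi) > 0:
            raise CalibrationError(
                f"incidence targets unreachable for gamma in [{glo}, {ghi}]: "
                f"g({glo})={g(glo):.3e}, g({ghi})={g(ghi):.3e}"
            )
        gamma = float(optimize.brentq(g, glo, ghi, xtol=1e-10))
    except ValueError as exc:  # pragma: no cover - defensive
        raise CalibrationError(f"gamma search failed: {exc}") from exc
    rate_c = rate_for(gamma)
    # fold the linear-predictor offset back into the rate:
    # (r t)^g e^(lp-off) = (r e^(-off/g) t)^g e^lp
    model = WeibullModel(gamma=gamma, rate=rate_c * np.exp(-offset / gamma), betas=tuple(betas))
    res10 = abs(marginal_incidence(model.rate, gamma, t_low, lp) - inc10)
    res25 = abs(marginal_incidence(model.rate, gamma, t_high, lp) - inc25)
    if max(res10, res25) > max(tol, 1e-4):
        raise CalibrationError(
            f"calibration residuals too large: {res10:.2e} at t={t_low}, {res25:.2e} at t={t_high}"
        )
    return model


def simulate_event_times(
    covariates: np.ndarray, model: WeibullModel, rng: np.random.Generator
) -> np.ndarray:
    """Latent event times by inversion: T = (-log U e^{-beta x})^(1/gamma) / rate."""
    lp = np.asarray(covariates, dtype=float) @ np.asarray(model.betas)
    u = rng.uniform(size=len(lp))
    return (-np.log(u) * np.exp(-lp)) ** (1.0 / model.gamma) / model.rate


def simulate_cohort(
    covariates: np.ndarray,
    model: WeibullModel,
    entry_window: float = 5.0,
    admin_end: float = 25.0,
    seed: int = 0,
    covariate_names: Sequence[str] | None = None,
    censor_from_entry: bool = True,
) -> Cohort:
    """Simulate a cohort with Weibull outcomes, staggered entry and an
    administrative study end.

    Entry offsets are Uniform(0, entry_window).  With ``censor_from_entry``
    (default) the study closes at calendar time ``admin_end``, so a subject
    entering at E is censored at ``admin_end - E`` on the time-from-entry
    scale (follow-up between ``admin_end - entry_window`` and ``admin_end``).
    With ``censor_from_entry=False`` every subject is censored at
    ``admin_end`` years of follow-up regardless of entry.
    """
    if entry_window < 0:
        raise ValueError("entry_window must be >= 0")
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    entry = rng.uniform(0.0, entry_window, size=n) if entry_window > 0 else np.zeros(n)
    t_event = simulate_event_times(x, model, rng)
    c = admin_end - entry if censor_from_entry else np.full(n, float(admin_end))
    exit_t = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    # exit > 0 is guaranteed almost surely; clip pathological zeros anyway
    exit_t = np.maximum(exit_t, 1e-12)
    if covariate_names is None:
        covariate_names = tuple(f"x{j}" for j in range(x.shape[1]))
    return Cohort(
        ids=np.arange(n),
        entry=entry,
        exit=exit_t,
        event=event,
        covariates=x,
        covariate_names=tuple(covariate_names),
    )


def incidence_by_horizon(cohort: Cohort, t: float) -> float:
    """Event proportion by time t among subjects followed at least t years.

    Subjects censored before t without an event are dropped from the
    denominator; subjects with events by t count in both.
    """
    known = (cohort.exit >= t) | ((cohort.event == 1) & (cohort.exit <= t))
    is_event = (cohort.event == 1) & (cohort.exit <= t)
    return float(is_event[known].mean())
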