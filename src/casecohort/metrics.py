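"""Predictive-ability measures adapted to case-cohort sampling.

Because cases are over-represented in a case-cohort set, standard measures
of discrimination computed on it are biased towards the null: case-case
pairs (which are harder to order) are over-represented for the C-index, and
the inflated overall risk compresses the spread of prognostic scores for
the D measure.  The adaptations here restore full-cohort behaviour:

* weighted C — relevant pairs are split into case-case and case-control
  comparisons; case-control pairs are up-weighted by 1/alpha,

      C_W = [n_c1 + 0.5 n_u1 + (1/a)(n_c0 + 0.5 n_u0)] / [n_r1 + (1/a) n_r0].

* weighted D — "weighted ranks" of the linear predictor give subcohort
  controls mass 1/alpha; Blom normal scores use the maximum weighted rank
  as the effective sample size; the coefficient of the scaled scores in a
  weighted Cox model (robust SE) is D_W.

* NRI — no reweighting is needed because movement proportions are formed
  within events and non-events separately, but non-subcohort cases whose
  event falls after the horizon t must be excluded (they would otherwise
  enrich the "non-event" group with future cases).  An alternative
  formulation keeps them and instead up-weights subcohort controls by
  1/alpha in the non-event portion.

All measures reduce exactly to their full-cohort versions at alpha = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .cohort import Cohort
from .design import CaseCohortDesign, full_cohort_design
from .cox import fit_weighted_cox, ConvergenceError

KAPPA = np.sqrt(np.pi / 8.0)  # scores scaled to variance pi/8, half-means +/-0.5


class NoRelevantPairsError(ValueError):
    """No pair of subjects has an observable risk ordering."""


@dataclass(frozen=True)
class PairCounts:
    """Relevant-pair tallies, split by comparison class.

    Second subscript 1 = case-case comparisons, 0 = case-control.
    """

    n_c1: float
    n_d1: float
    n_u1: float
    n_c0: float
    n_d0: float
    n_u0: float

    @property
    def n_r1(self) -> float:
        return self.n_c1 + self.n_d1 + self.n_u1

    @property
    def n_r0(self) -> float:
        return self.n_c0 + self.n_d0 + self.n_u0

    @property
    def n_relevant(self) -> float:
        return self.n_r1 + self.n_r0


@dataclass(frozen=True)
class ConcordanceResult:
    estimate: float
    se: float
    pair_counts: PairCounts
    alpha: float
    n: int

    def as_record(self) -> dict:
        pc = self.pair_counts
        return {
            "metric": "c_w" if self.alpha != 1.0 else "c",
            "estimate": self.estimate,
            "se_analytical": self.se,
            "alpha": self.alpha,
            "n": self.n,
            "n_relevant_case_case": pc.n_r1,
            "n_relevant_case_control": pc.n_r0,
        }


@dataclass(frozen=True)
class DResult:
    estimate: float
    se: float
    z: np.ndarray
    kappa: float = KAPPA
    degenerate: bool = False

    def as_record(self) -> dict:
        return {
            "metric": "d",
            "estimate": self.estimate,
            "se_analytical": self.se,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class NriResult:
    nri: float
    nri_events: float
    nri_nonevents: float
    se_analytical: float
    n_events: float
    n_nonevents: float
    events_up: float
    events_down: float
    nonevents_up: float
    nonevents_down: float
    excluded_late_cases: int
    excluded_censored: int
    se_bootstrap: float | None = None

    def as_record(self) -> dict:
        return {
            "metric": "nri",
            "estimate": self.nri,
            "nri_events": self.nri_events,
            "nri_nonevents": self.nri_nonevents,
            "se_analytical": self.se_analytical,
            "se_bootstrap": self.se_bootstrap,
            "n_events": self.n_events,
            "n_nonevents": self.n_nonevents,
            "events_up": self.events_up,
            "events_down": self.events_down,
            "nonevents_up": self.nonevents_up,
            "nonevents_down": self.nonevents_down,
            "excluded_late_cases": self.excluded_late_cases,
            "excluded_censored": self.excluded_censored,
        }


# ---------------------------------------------------------------------------
# concordance

def _pair_scan(
    lp: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    alpha: float,
    chunk: int = 384,
):
    """Enumerate relevant pairs in chunks.

    A pair is relevant iff the member with the strictly shorter observed
    time has an event (equal times are never relevant: no ordering is
    observed).  Concordance credit is 1 if that member also has the higher
    linear predictor, 0.5 on a predictor tie, else 0.  Case-control pairs
    (the longer-time member is not a case) carry weight 1/alpha.

    Returns raw class counts plus per-subject weighted numerator and
    denominator sums for the leave-one-out jackknife.
    """
    n = len(lp)
    ev = event == 1
    counts = np.zeros(6)  # c1, d1, u1, c0, d0, u0
    num_i = np.zeros(n)
    den_i = np.zeros(n)
    w0 = 1.0 / alpha
    total_num = 0.0
    total_den = 0.0
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        rel = ev[s:e, None] & (time[s:e, None] < time[None, :])
        if not rel.any():
            continue
        higher = lp[s:e, None] > lp[None, :]
        lower = lp[s:e, None] < lp[None, :]
        tie = rel & ~higher & ~lower
        conc = rel & higher
        disc = rel & lower
        cc = ev[None, :]  # longer-time member is a (future) case
        counts[0] += np.count_nonzero(conc & cc)
        counts[1] += np.count_nonzero(disc & cc)
        counts[2] += np.count_nonzero(tie & cc)
        counts[3] += np.count_nonzero(conc & ~cc)
        counts[4] += np.count_nonzero(disc & ~cc)
        counts[5] += np.count_nonzero(tie & ~cc)
        w = np.where(cc, 1.0, w0) * rel
        credit = w * (conc + 0.5 * tie)
        total_num += credit.sum()
        total_den += w.sum()
        num_i[s:e] += credit.sum(axis=1)
        num_i += credit.sum(axis=0)
        den_i[s:e] += w.sum(axis=1)
        den_i += w.sum(axis=0)
    return counts, total_num, total_den, num_i, den_i


def _concordance(lp, time, event, alpha: float) -> ConcordanceResult:
    lp = np.asarray(lp, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    counts, num, den, num_i, den_i = _pair_scan(lp, time, event, alpha)
    pc = PairCounts(*counts)
    if pc.n_relevant == 0:
        raise NoRelevantPairsError("no relevant pairs: concordance is undefined")
    c = num / den
    # leave-one-subject-out jackknife on the weighted pair sums
    den_loo = den - den_i
    with np.errstate(invalid="ignore", divide="ignore"):
        c_loo = np.where(den_loo > 0, (num - num_i) / den_loo, c)
    n = len(lp)
    se = float(np.sqrt((n - 1) / n * np.sum((c_loo - c_loo.mean()) ** 2)))
    return ConcordanceResult(estimate=float(c), se=se, pair_counts=pc, alpha=alpha, n=n)


def harrell_c(lp, time, event) -> ConcordanceResult:
    """Harrell's C-index: (n_c + 0.5 n_u) / n_r over relevant pairs.

    0.5 means no discrimination beyond chance; 1 perfect discrimination.
    The SE is a leave-one-subject-out jackknife.
    """
    return _concordance(lp, time, event, alpha=1.0)


def _member_arrays(values, design: CaseCohortDesign) -> np.ndarray:
    """Accept arrays over the full cohort or over the case-cohort set."""
    values = np.asarray(values)
    members = design.member_indices()
    if len(values) == len(design.cohort):
        return values[members]
    if len(values) == len(members):
        return values
    raise ValueError(
        f"array length {len(values)} matches neither the cohort "
        f"({len(design.cohort)}) nor the case-cohort set ({len(members)})"
    )


def weighted_c(lp, design: CaseCohortDesign, time=None, event=None) -> ConcordanceResult:
    """Case-cohort weighted C-index with 1/alpha weight on case-control pairs.

    ``lp`` may cover the full cohort or just the case-cohort set (cohort
    order); times/events default to the design's cohort.  All cases are
    treated alike whether or not they are in the subcohort; controls are
    non-case subcohort members.
    """
    members = design.member_indices()
    cohort = design.cohort
    lp_m = _member_arrays(lp, design)
    time_m = cohort.exit[members] if time is None else _member_arrays(time, design)
    event_m = cohort.event[members] if event is None else _member_arrays(event, design)
    return _concordance(lp_m, time_m, event_m, alpha=design.alpha)


# ---------------------------------------------------------------------------
# Royston-Sauerbrei D

def blom_scores(weighted_ranks, effective_n: float) -> np.ndarray:
    """Normal order scores via Blom's approximation, scaled by sqrt(pi/8).

    ``z_r = Phi^-1((r - 3/8) / (n + 1/4)) * sqrt(pi/8)``.  With plain ranks
    and ``effective_n = n`` these are the standard scores; with weighted
    ranks, ``effective_n`` is the maximum weighted rank, approximating the
    full-cohort size.
    """
    r = np.asarray(weighted_ranks, dtype=float)
    if np.any(r <= 0):
        raise ValueError("ranks must be positive")
    if np.any(r > effective_n * (1 + 1e-12) + 1e-9):
        raise ValueError("rank exceeds the effective sample size")
    return stats.norm.ppf((r - 0.375) / (effective_n + 0.25)) * KAPPA


def _weighted_ranks(lp: np.ndarray, mass: np.ndarray) -> tuple[np.ndarray, float]:
    """Cumulative-mass ranks ordered by lp; tied lp share the block mean."""
    order = np.argsort(lp, kind="stable")
    cum = np.cumsum(mass[order])
    total = float(cum[-1])
    lp_sorted = lp[order]
    ranks_sorted = cum.copy()
    # average cumulative mass over blocks of exactly tied lp
    block_start = np.flatnonzero(np.concatenate([[True], lp_sorted[1:] != lp_sorted[:-1]]))
    block_id = np.cumsum(np.isin(np.arange(len(lp)), block_start)) - 1
    sums = np.bincount(block_id, weights=ranks_sorted)
    cnts = np.bincount(block_id)
    ranks_sorted = (sums / cnts)[block_id]
    ranks = np.empty_like(ranks_sorted)
    ranks[order] = ranks_sorted
    return ranks, total


def royston_d(
    lp,
    design: CaseCohortDesign | Cohort,
    scheme: str = "prentice",
) -> DResult:
    """Royston and Sauerbrei's D, or its case-cohort weighted version D_W.

    Full-cohort path (a :class:`Cohort`, or a design with alpha = 1): the
    linear predictors are ranked, Blom-transformed and scaled by sqrt(pi/8)
    to give z ~ N(0, pi/8); a second Cox model on z yields D as the
    coefficient of z, interpretable as the log hazard ratio between the
    higher- and lower-risk halves of the cohort.

    Case-cohort path: ranks accumulate mass 1 for every case and 1/alpha for
    each subcohort control; Blom uses the maximum weighted rank as the
    sample size; the second-stage model is the scheme's weighted Cox
    pseudolikelihood and the SE is robust.

    A constant predictor returns D = 0 with ``degenerate=True``.
    """
    if isinstance(design, Cohort):
        design = full_cohort_design(design)
    members = design.member_indices()
    cohort = design.cohort
    lp_m = np.asarray(_member_arrays(lp, design), dtype=float)
    full = design.alpha == 1.0 and bool(design.in_subcohort.all())
    if full:
        mass = np.ones(len(members))
    else:
        controls = design.cohort.event[members] == 0
        mass = np.where(controls, 1.0 / design.alpha, 1.0)
    ranks, effective_n = _weighted_ranks(lp_m, mass)
    z = blom_scores(ranks, effective_n)
    sub_cohort = Cohort(
        ids=cohort.ids[members],
        entry=cohort.entry[members],
        exit=cohort.exit[members],
        event=cohort.event[members],
        covariates=z.reshape(-1, 1),
        covariate_names=("z",),
    )
    sub_design = CaseCohortDesign(
        cohort=sub_cohort, alpha=design.alpha, in_subcohort=design.in_subcohort[members]
    )
    try:
        fit = fit_weighted_cox(sub_design, scheme=scheme)
    except ValueError:
        return DResult(estimate=0.0, se=float("nan"), z=z, degenerate=True)
    se = float(fit.se_naive[0]) if full else float(fit.se_robust[0])
    return DResult(estimate=float(fit.betas[0]), se=se, z=z)


# ---------------------------------------------------------------------------
# net reclassification improvement

@dataclass(frozen=True)
class NriEligibility:
    """Subjects usable for an NRI at horizon t, with status labels.

    ``indices`` point into the design's cohort; ``is_event`` labels event
    status at t.  Exclusions: subjects censored before t without an event
    (status unknown), and non-subcohort cases whose event falls after t
    (keeping them would enrich the non-event group with future cases).
    """

    indices: np.ndarray
    is_event: np.ndarray
    is_late_case: np.ndarray  # among kept subjects: event after t (subcohort)
    excluded_late_cases: int
    excluded_censored: int
    horizon: float


def nri_eligibility(design: CaseCohortDesign, t: float) -> NriEligibility:
    """Classify case-cohort members for an NRI with horizon ``t``."""
    if t <= 0:
        raise ValueError("horizon t must be > 0")
    cohort = design.cohort
    members = design.member_indices()
    exit_m = cohort.exit[members]
    event_m = cohort.event[members]
    sub_m = design.in_subcohort[members]
    is_event = (event_m == 1) & (exit_m <= t)
    known_nonevent = exit_m > t
    late_case = (event_m == 1) & (exit_m > t)
    censored_early = ~is_event & ~known_nonevent
    exclude = censored_early | (late_case & ~sub_m)
    keep = ~exclude
    return NriEligibility(
        indices=members[keep],
        is_event=is_event[keep],
        is_late_case=(late_case & sub_m)[keep],
        excluded_late_cases=int(np.count_nonzero(late_case & ~sub_m)),
        excluded_censored=int(np.count_nonzero(censored_early)),
        horizon=t,
    )


def _movements(
    old: np.ndarray, new: np.ndarray, mode: str, boundaries: Sequence[float] | None
) -> tuple[np.ndarray, np.ndarray]:
    if np.any((old < 0) | (old > 1) | (new < 0) | (new > 1)):
        raise ValueError("risks must lie in [0, 1]")
    if mode == "categories":
        if not boundaries:
            raise ValueError("category mode needs boundary values")
        b = np.asarray(boundaries, dtype=float)
        cat_old = np.searchsorted(b, old, side="right")
        cat_new = np.searchsorted(b, new, side="right")
        return cat_new > cat_old, cat_new < cat_old
    if mode == "continuous":
        return new > old, new < old
    raise ValueError(f"unknown NRI mode '{mode}'")


def _nri_from_movements(up, down, is_event, w=None):
    if w is None:
        w = np.ones(len(up))
    e = is_event
    ne = ~is_event
    n_e = float(w[e].sum())
    n_ne = float(w[ne].sum())
    if n_e == 0:
        raise ValueError("no eligible events: NRI undefined")
    if n_ne == 0:
        raise ValueError("no eligible non-events: NRI undefined")
    up_e = float(w[e & up].sum())
    down_e = float(w[e & down].sum())
    up_ne = float(w[ne & up].sum())
    down_ne = float(w[ne & down].sum())
    nri_e = (up_e - down_e) / n_e
    nri_ne = (down_ne - up_ne) / n_ne
    return nri_e, nri_ne, (up_e, down_e, up_ne, down_ne, n_e, n_ne)


def _analytic_se(up_e, down_e, up_ne, down_ne, n_e, n_ne) -> float:
    """Binomial-difference SE for the two NRI components.

    Known to understate the true variability for case-cohort data, where
    the risk estimates themselves carry sampling error; bootstrap SEs are
    the recommended alternative there.
    """
    pe_u, pe_d = up_e / n_e, down_e / n_e
    pn_u, pn_d = up_ne / n_ne, down_ne / n_ne
    var = (pe_u + pe_d - (pe_u - pe_d) ** 2) / n_e + (pn_u + pn_d - (pn_d - pn_u) ** 2) / n_ne
    return float(np.sqrt(max(var, 0.0)))


def nri(
    risks_old,
    risks_new,
    eligibility: NriEligibility,
    mode: str = "categories",
    boundaries: Sequence[float] | None = (0.10, 0.20),
) -> NriResult:
    """Net reclassification improvement at the eligibility horizon.

    ``risks_old`` / ``risks_new`` are absolute risks at the horizon, indexed
    like the design's cohort or like ``eligibility.indices``.  Category mode
    counts moves across ``boundaries`` (half-open upward: a risk equal to a
    boundary falls in the higher category); continuous mode counts any
    strict change in predicted risk.  No sampling weights enter: movement
    proportions are computed within events and non-events separately, which
    is what makes the measure design-robust once the exclusion rule has
    been applied.
    """
    old = np.asarray(risks_old, dtype=float)
    new = np.asarray(risks_new, dtype=float)
    if len(old) != len(eligibility.indices):
        old = old[eligibility.indices]
        new = new[eligibility.indices]
    up, down = _movements(old, new, mode, boundaries)
    nri_e, nri_ne, (up_e, down_e, up_ne, down_ne, n_e, n_ne) = _nri_from_movements(
        up, down, eligibility.is_event
    )
    return NriResult(
        nri=nri_e + nri_ne,
        nri_events=nri_e,
        nri_nonevents=nri_ne,
        se_analytical=_analytic_se(up_e, down_e, up_ne, down_ne, n_e, n_ne),
        n_events=n_e,
        n_nonevents=n_ne,
        events_up=up_e,
        events_down=down_e,
        nonevents_up=up_ne,
        nonevents_down=down_ne,
        excluded_late_cases=eligibility.excluded_late_cases,
        excluded_censored=eligibility.excluded_censored,
    )


def nri_weighted_alternative(
    risks_old,
    risks_new,
    design: CaseCohortDesign,
    t: float,
    mode: str = "categories",
    boundaries: Sequence[float] | None = (0.10, 0.20),
) -> NriResult:
    """NRI variant that keeps non-subcohort late cases instead of excluding them.

    The non-event portion then contains three groups — subcohort late cases
    (weight 1), non-subcohort late cases (weight 1) and subcohort controls
    (weight 1/alpha) — with weighted movement proportions; the event portion
    is unchanged.  At alpha = 1 this equals the standard NRI exactly.
    """
    if t <= 0:
        raise ValueError("horizon t must be > 0")
    cohort = design.cohort
    members = design.member_indices()
    exit_m = cohort.exit[members]
    event_m = cohort.event[members]
    is_event = (event_m == 1) & (exit_m <= t)
    known_nonevent = exit_m > t
    keep = is_event | known_nonevent
    censored_early = int(np.count_nonzero(~keep))
    old = np.asarray(risks_old, dtype=float)
    new = np.asarray(risks_new, dtype=float)
    if len(old) == len(cohort):
        old, new = old[members], new[members]
    elif len(old) != len(members):
        raise ValueError("risk arrays match neither the cohort nor the case-cohort set")
    old, new = old[keep], new[keep]
    ev = is_event[keep]
    late_case = ((event_m == 1) & (exit_m > t))[keep]
    w = np.ones(len(old))
    controls = ~ev & ~late_case  # non-cases followed beyond t (subcohort members)
    w[controls] = 1.0 / design.alpha
    up, down = _movements(old, new, mode, boundaries)
    nri_e, nri_ne, (up_e, down_e, up_ne, down_ne, n_e, n_ne) = _nri_from_movements(
        up, down, ev, w=w
    )
    n_ne_subjects = float(np.count_nonzero(~ev))
    return NriResult(
        nri=nri_e + nri_ne,
        nri_events=nri_e,
        nri_nonevents=nri_ne,
        se_analytical=_analytic_se(up_e, down_e, up_ne, down_ne, n_e, n_ne_subjects),
        n_events=n_e,
        n_nonevents=n_ne,
        events_up=up_e,
        events_down=down_e,
        nonevents_up=up_ne,
        nonevents_down=down_ne,
        excluded_late_cases=0,
        excluded_censored=censored_early,
    )


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_se(
    metric: Callable[[CaseCohortDesign], float],
    design: CaseCohortDesign,
    B: int = 200,
    seed: int = 0,
    max_failure_fraction: float = 0.10,
) -> float:
    """Design-preserving bootstrap SE of a metric on a case-cohort design.

    Subjects are resampled with replacement separately within the subcohort
    and within the non-subcohort cases, so every replicate is again a valid
    case-cohort design with the same alpha and group sizes.  ``metric`` is
    called on each replicate design (refitting models inside the closure if
    desired); the SD across replicates is returned.
    """
    if B < 50:
        raise ValueError("B must be >= 50 for a usable bootstrap SE")
    rng = np.random.default_rng(seed)
    cohort = design.cohort
    sub_idx = np.flatnonzero(design.in_subcohort)
    ns_case_idx = np.flatnonzero(~design.in_subcohort & design.is_case)
    values = []
    failures = []
    for b in range(B):
        take_sub = rng.choice(sub_idx, size=len(sub_idx), replace=True)
        take_ns = rng.choice(ns_case_idx, size=len(ns_case_idx), replace=True)
        take = np.concatenate([take_sub, take_ns])
        boot_cohort = Cohort(
            ids=np.arange(len(take)),
            entry=cohort.entry[take],
            exit=cohort.exit[take],
            event=cohort.event[take],
            covariates=cohort.covariates[take],
            covariate_names=cohort.covariate_names,
        )
        flags = np.zeros(len(take), dtype=bool)
        flags[: len(take_sub)] = True
        boot_design = CaseCohortDesign(
            cohort=boot_cohort, alpha=design.alpha, in_subcohort=flags
        )
        try:
            values.append(float(metric(boot_design)))
        except (ValueError, ZeroDivisionError, ConvergenceError) as exc:
            failures.append((b, repr(exc)))
    if len(failures) > max_failure_fraction * B:
        raise RuntimeError(
            f"metric failed in {len(failures)}/{B} bootstrap replicates; "
            f"first failures: {failures[:3]}"
        )
    return float(np.std(values, ddof=1))


def export_results(results, path, sep: str = ",") -> None:
    """Write metric results (objects with ``as_record``) as delimited text."""
    import pandas as pd

    pd.DataFrame.from_records([r.as_record() for r in results]).to_csv(
        path, sep=sep, index=False
    )
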