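"""Case-cohort design: subcohort sampling, roles, and scheme risk sets.

A case-cohort study measures covariates on a random subcohort (sampling
fraction alpha) plus every case in the full cohort.  Estimation uses a
weighted Cox pseudolikelihood in which non-subcohort cases are not at risk
until immediately before their own event.  Three classical weighting
schemes are supported:

* ``prentice`` — subcohort members at risk carry weight 1; a non-subcohort
  case enters the risk set only at its own event time, with weight 1.
* ``self_prentice`` — denominators contain subcohort members only; a
  non-subcohort case contributes its event to the numerator but never to
  any denominator.
* ``barlow`` — subcohort controls and future cases at risk carry weight
  1/alpha, mimicking full-cohort proportions; any subject at its own event
  time (subcohort or not) carries weight 1.

At alpha = 1 all three reduce exactly to the full-cohort Cox risk sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

SCHEMES = ("prentice", "self_prentice", "barlow")


def _check_scheme(scheme: str) -> str:
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme '{scheme}'; choose one of {SCHEMES}")
    return scheme


@dataclass(frozen=True)
class CaseCohortDesign:
    """A drawn case-cohort design over a cohort.

    ``in_subcohort`` flags the random subcohort; ``is_case`` flags subjects
    with an observed event at any time.  The case-cohort set (subjects with
    covariates available) is ``in_subcohort | is_case``.
    """

    cohort: Cohort
    alpha: float
    in_subcohort: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        flags = np.asarray(self.in_subcohort, dtype=bool)
        if len(flags) != len(self.cohort):
            raise ValueError("in_subcohort length must match the cohort")
        object.__setattr__(self, "in_subcohort", flags)

    @property
    def is_case(self) -> np.ndarray:
        return self.cohort.event == 1

    @property
    def in_set(self) -> np.ndarray:
        """Membership in the case-cohort set (subcohort union cases)."""
        return self.in_subcohort | self.is_case

    @property
    def subcohort_size(self) -> int:
        return int(self.in_subcohort.sum())

    def member_indices(self) -> np.ndarray:
        """Indices (into the cohort) of the case-cohort set, in cohort order."""
        return np.flatnonzero(self.in_set)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.cohort.ids,
                "in_subcohort": self.in_subcohort.astype(int),
                "is_case": self.is_case.astype(int),
            }
        )

    def export(self, path, sep: str = ",") -> None:
        """Write id / in_subcohort / is_case flags as delimited text."""
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_flags(cls, cohort: Cohort, alpha: float, in_subcohort) -> "CaseCohortDesign":
        return cls(cohort=cohort, alpha=float(alpha), in_subcohort=np.asarray(in_subcohort, dtype=bool))


def draw_case_cohort(cohort: Cohort, alpha: float, seed: int) -> CaseCohortDesign:
    """Draw the subcohort as a without-replacement sample of size round(alpha N).

    All cases are in the case-cohort set by construction; the draw is
    deterministic given the seed.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    n = len(cohort)
    k = int(round(alpha * n))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=k, replace=False)
    flags = np.zeros(n, dtype=bool)
    flags[chosen] = True
    return CaseCohortDesign(cohort=cohort, alpha=alpha, in_subcohort=flags)


def full_cohort_design(cohort: Cohort) -> CaseCohortDesign:
    """The degenerate alpha = 1 design: everyone in the subcohort."""
    return CaseCohortDesign(cohort=cohort, alpha=1.0, in_subcohort=np.ones(len(cohort), dtype=bool))


def risk_set(
    design: CaseCohortDesign, scheme: str, event_time: float, event_subject
) -> pd.DataFrame:
    """Weighted risk-set membership at one event time.

    Returns a data frame (id, weight) of denominator members with their
    scheme weights.  ``event_subject`` must be the id of a subject with an
    event at ``event_time``; with Breslow tie handling, subjects tied at the
    same event time share this denominator.

    At-risk status on the time-from-entry scale means ``exit >= event_time``
    (a subject leaving at exactly t is still in the risk set at t).
    """
    _check_scheme(scheme)
    cohort = design.cohort
    idx = np.flatnonzero(cohort.ids == event_subject)
    if len(idx) != 1:
        raise ValueError(f"unknown subject id {event_subject!r}")
    i = idx[0]
    if cohort.event[i] != 1 or not np.isclose(cohort.exit[i], event_time):
        raise ValueError(
            f"subject {event_subject!r} does not have an event at t={event_time}"
        )
    at_risk = cohort.exit >= event_time
    sub = design.in_subcohort
    tied_event = (cohort.event == 1) & np.isclose(cohort.exit, event_time)

    if scheme == "self_prentice":
        member = sub & at_risk
        weight = np.ones(len(cohort))
    elif scheme == "prentice":
        member = (sub & at_risk) | (tied_event & ~sub)
        weight = np.ones(len(cohort))
    else:  # barlow
        member = (sub & at_risk) | (tied_event & ~sub)
        weight = np.full(len(cohort), 1.0 / design.alpha)
        weight[tied_event] = 1.0
    out = pd.DataFrame({"id": cohort.ids[member], "weight": weight[member]})
    return out.reset_index(drop=True)
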