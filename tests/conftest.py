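"""Shared fixtures: small synthetic cohorts, hand-built design fixtures, and
the session-scoped benchmark sweeps used by the acceptance tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from casecohort.cohort import Cohort
from casecohort.simulate import CovariateSpec, WeibullModel, generate_covariates, simulate_cohort
from casecohort.design import CaseCohortDesign, full_cohort_design


@pytest.fixture(scope="session")
def small_spec() -> CovariateSpec:
    return CovariateSpec(
        names=("age", "smoke"),
        kinds=("continuous", "binary"),
        means=(50.0, 0.4),
        sds=(10.0, 0.0),
    )


@pytest.fixture(scope="session")
def small_model() -> WeibullModel:
    # ~30% cumulative incidence by 25 years at the covariate means
    return WeibullModel(gamma=1.4, rate=0.005, betas=(0.03, 0.5))


@pytest.fixture(scope="session")
def make_cohort(small_spec, small_model):
    """Factory for seeded synthetic cohorts with the two-covariate model."""

    def _make(n: int = 500, seed: int = 0, **kwargs) -> Cohort:
        x = generate_covariates(n, small_spec, seed=seed)
        return simulate_cohort(
            x, small_model, seed=seed + 1, covariate_names=small_spec.names, **kwargs
        )

    return _make


@pytest.fixture()
def five_subject_design() -> CaseCohortDesign:
    """Hand-enumerable design: subcohort {0, 2, 4}, cases {0 (t=2), 1 (t=4)}.

    Subject 1 is a case outside the subcohort; subject 3 is outside both the
    subcohort and the case set (no covariate data in a real study).
    """
    cohort = Cohort(
        ids=np.arange(5),
        entry=np.zeros(5),
        exit=np.array([2.0, 4.0, 5.0, 1.5, 3.0]),
        event=np.array([1, 1, 0, 0, 0]),
        covariates=np.array([[0.5], [1.0], [-0.5], [0.2], [0.0]]),
        covariate_names=("x",),
    )
    flags = np.array([True, False, True, False, True])
    return CaseCohortDesign(cohort=cohort, alpha=0.6, in_subcohort=flags)


@pytest.fixture()
def four_subject_concordance():
    """Two cases, two subcohort controls, alpha = 0.5; pairs enumerable by hand.

    Relevant pairs: (A,B) case-case concordant; (A,C), (A,D), (B,C)
    case-control concordant; (B,D) case-control discordant; C-D not relevant.
    C_W = (1 + 2*3) / (1 + 2*4) = 7/9; unweighted C = 4/5.
    """
    cohort = Cohort(
        ids=np.array(["A", "B", "C", "D"]),
        entry=np.zeros(4),
        exit=np.array([1.0, 2.0, 3.0, 4.0]),
        event=np.array([1, 1, 0, 0]),
        covariates=np.array([[3.0], [2.0], [1.0], [2.5]]),
        covariate_names=("lp",),
    )
    design = CaseCohortDesign(
        cohort=cohort, alpha=0.5, in_subcohort=np.array([False, True, True, True])
    )
    return cohort, design


# ---------------------------------------------------------------------------
# benchmark sweeps (shared by the acceptance tests; lazily built)

BENCH_REPLICATES = 100
BENCH_SEED = 20130913


@pytest.fixture(scope="session")
def chd_high_records() -> pd.DataFrame:
    """Replicate records of the high-incidence CHD benchmark."""
    from casecohort.study import SweepConfig, run_sweep

    cfg = SweepConfig(
        replicates=BENCH_REPLICATES,
        fractions=(0.03, 0.1, 0.3, 0.5, 0.9),
        base_seed=BENCH_SEED,
    )
    return run_sweep(cfg)


@pytest.fixture(scope="session")
def chd_low_records() -> pd.DataFrame:
    """Replicate records of the halved-rate (low incidence) benchmark."""
    from casecohort.study import SweepConfig, run_sweep

    cfg = SweepConfig(
        replicates=BENCH_REPLICATES,
        fractions=(0.1,),
        low_incidence=True,
        base_seed=BENCH_SEED,
    )
    return run_sweep(cfg)


@pytest.fixture(scope="session")
def chd_context():
    """One fixed CHD covariate matrix and calibrated generating model."""
    from casecohort.study import SweepConfig, ScenarioContext

    return ScenarioContext.build(SweepConfig(base_seed=BENCH_SEED))
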