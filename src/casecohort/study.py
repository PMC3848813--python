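"""Simulation benchmark: full-cohort versus case-cohort estimation.

Each replicate simulates a fresh outcome realisation for a fixed covariate
matrix, derives risk models and predictive-ability measures on the full
cohort (the gold standard), then draws a case-cohort design at a given
sampling fraction and recomputes everything with the case-cohort methods —
both the naive unweighted measures and the weighted adaptations.
Aggregation over replicates yields bias, analytical/empirical SEs and
relative efficiencies per sampling fraction, in the layout of a
two-incidence benchmark study (high incidence, and the same generating
model with the Weibull rate halved).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .simulate import (
    CovariateSpec,
    WeibullModel,
    betas_per_unit,
    calibrate_weibull,
    generate_covariates,
    simulate_cohort,
    incidence_by_horizon,
)
from .design import draw_case_cohort, full_cohort_design
from .cox import fit_weighted_cox, breslow_baseline, predict_absolute_risk
from .metrics import harrell_c, weighted_c, royston_d, nri_eligibility, nri

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# the illustrative CHD cohort configuration

def chd_covariate_spec(with_hdl: bool = True) -> CovariateSpec:
    """Covariate distributions of the illustrative CHD cohort.

    Middle-aged male cohort: age 52.3 (7.6) years, 53.3% smokers, systolic
    blood pressure 141.8 (20.6) mmHg, total cholesterol 6.3 (1.0) mmol/l,
    HDL-cholesterol 1.4 (0.2) mmol/l.  Covariates are independent by
    default; build a ``CovariateSpec`` with a correlation matrix directly
    for sensitivity analyses.
    """
    names = ["age", "smoking", "sbp", "tchol"]
    kinds = ["continuous", "binary", "continuous", "continuous"]
    means = [52.3, 0.533, 141.8, 6.3]
    sds = [7.6, 0.0, 20.6, 1.0]
    if with_hdl:
        names.append("hdl")
        kinds.append("continuous")
        means.append(1.4)
        sds.append(0.2)
    return CovariateSpec(names=tuple(names), kinds=tuple(kinds), means=tuple(means), sds=tuple(sds))


#: hazard ratios per SD (continuous) or per category (binary) for the
#: four-covariate CHD model and the five-covariate model adding HDL
CHD_MODEL1_HRS = {"age": 1.68, "smoking": 1.54, "sbp": 1.22, "tchol": 1.31}
CHD_MODEL2_HRS = {"age": 1.65, "smoking": 1.51, "sbp": 1.22, "tchol": 1.27, "hdl": 0.80}


def chd_generating_model(
    spec: CovariateSpec | None = None,
    inc10: float = 0.073,
    inc25: float = 0.277,
    low_incidence: bool = False,
) -> WeibullModel:
    """Weibull generating model for the CHD example.

    True log hazard ratios are the five-covariate model's, converted to the
    raw covariate scale; (rate, gamma) are calibrated so the marginal
    cumulative incidence hits ``inc10`` at 10 years and ``inc25`` at 25.
    ``low_incidence`` halves the calibrated rate afterwards (it does not
    recalibrate), cutting the 10-year incidence to roughly a third.
    """
    spec = spec or chd_covariate_spec()
    per_sd = [np.log(CHD_MODEL2_HRS[n]) if n in CHD_MODEL2_HRS else 0.0 for n in spec.names]
    betas = betas_per_unit(per_sd, spec)
    model = calibrate_weibull(spec, betas, inc10, inc25)
    return model.halved_rate() if low_incidence else model


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of a full sweep over subcohort sampling fractions."""

    n: int = 6773
    spec: CovariateSpec = field(default_factory=chd_covariate_spec)
    model1: tuple[str, ...] = ("age", "smoking", "sbp", "tchol")
    model2: tuple[str, ...] = ("age", "smoking", "sbp", "tchol", "hdl")
    inc10: float = 0.073
    inc25: float = 0.277
    low_incidence: bool = False
    fractions: tuple[float, ...] = (0.03, 0.1, 0.3, 0.5, 0.9)
    replicates: int = 100
    scheme: str = "prentice"
    horizon: float = 10.0
    categories: tuple[float, ...] = (0.10, 0.20)
    entry_window: float = 5.0
    admin_end: float = 25.0
    base_seed: int = 20130913

    def __post_init__(self) -> None:
        if not all(0 < f <= 1 for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SweepConfig":
        d = dict(d)
        if "spec" in d and isinstance(d["spec"], dict):
            d["spec"] = CovariateSpec.from_dict(d["spec"])
        for key in ("model1", "model2", "fractions", "categories"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ScenarioContext:
    """Fixed-per-scenario inputs: covariate matrix and generating model.

    The covariate matrix is drawn once per scenario and reused across
    replicates (emulating repeated outcome realisations for one cohort);
    only the outcome and design streams are re-drawn per replicate.
    """

    config: SweepConfig
    covariates: np.ndarray
    model: WeibullModel

    @classmethod
    def build(cls, config: SweepConfig) -> "ScenarioContext":
        x = generate_covariates(config.n, config.spec, seed=config.base_seed)
        model = chd_generating_model(
            config.spec, config.inc10, config.inc25, low_incidence=config.low_incidence
        )
        return cls(config=config, covariates=x, model=model)

    def simulate(self, seed: int) -> Cohort:
        return simulate_cohort(
            self.covariates,
            self.model,
            entry_window=self.config.entry_window,
            admin_end=self.config.admin_end,
            seed=seed,
            covariate_names=self.config.spec.names,
        )


def _subset_cohort(cohort: Cohort, members: np.ndarray) -> Cohort:
    return Cohort(
        ids=cohort.ids[members],
        entry=cohort.entry[members],
        exit=cohort.exit[members],
        event=cohort.event[members],
        covariates=cohort.covariates[members],
        covariate_names=cohort.covariate_names,
    )


def _metric_block(lp, design, scheme, full=False):
    """C and D on one analysis set: naive (unweighted) and weighted."""
    cohort = design.cohort
    members = design.member_indices()
    out = {}
    cu = harrell_c(lp[members], cohort.exit[members], cohort.event[members])
    out["c_uw"], out["c_uw_se"] = cu.estimate, cu.se
    du = royston_d(lp[members], _subset_cohort(cohort, members))
    out["d_uw"], out["d_uw_se"] = du.estimate, du.se
    if full:
        out["c_w"], out["c_w_se"] = cu.estimate, cu.se
        out["d_w"], out["d_w_se"] = du.estimate, du.se
    else:
        cw = weighted_c(lp, design)
        out["c_w"], out["c_w_se"] = cw.estimate, cw.se
        dw = royston_d(lp, design, scheme=scheme)
        out["d_w"], out["d_w_se"] = dw.estimate, dw.se
    return out


def _full_stage(ctx: ScenarioContext, seed: int) -> dict:
    """Simulate one cohort and compute every full-cohort (gold standard) quantity."""
    cfg = ctx.config
    ss = np.random.SeedSequence(entropy=(int(seed), 811_421))
    outcome_seed, design_seed = (int(s) % 2**31 for s in ss.generate_state(2))
    cohort = ctx.simulate(outcome_seed)
    rec: dict = {"seed": seed, "n_events": cohort.n_events}
    rec["inc10"] = incidence_by_horizon(cohort, cfg.horizon)
    full = full_cohort_design(cohort)
    fit1 = fit_weighted_cox(full, covariate_names=cfg.model1)
    fit2 = fit_weighted_cox(full, covariate_names=cfg.model2)
    lp1 = fit1.linear_predictor(cohort.covariate_matrix(cfg.model1))
    for k, v in _metric_block(lp1, full, cfg.scheme, full=True).items():
        rec[f"full_{k}"] = v
    b1 = breslow_baseline(fit1, full)
    b2 = breslow_baseline(fit2, full)
    risk1 = predict_absolute_risk(fit1, b1, cohort.covariate_matrix(cfg.model1), cfg.horizon)
    risk2 = predict_absolute_risk(fit2, b2, cohort.covariate_matrix(cfg.model2), cfg.horizon)
    elig = nri_eligibility(full, cfg.horizon)
    for mode, key in (("categories", "cat"), ("continuous", "cont")):
        res = nri(risk1, risk2, elig, mode=mode, boundaries=cfg.categories)
        rec[f"full_nri_{key}"] = res.nri
        rec[f"full_nri_{key}_se"] = res.se_analytical
        rec[f"full_nri_{key}_events"] = res.nri_events
        rec[f"full_nri_{key}_nonevents"] = res.nri_nonevents
    return {
        "record": rec,
        "cohort": cohort,
        "full": full,
        "fit1": fit1,
        "risk1": risk1,
        "design_seed": design_seed,
    }


def run_replicate(
    ctx: ScenarioContext, fraction: float, seed: int, _full_stage_out: dict | None = None
) -> dict:
    """One full-cohort/case-cohort comparison replicate; deterministic by seed.

    Simulates a cohort, derives the four- and five-covariate models and all
    measures on the full cohort (gold standard), draws the case-cohort
    design, refits with the weighted pseudolikelihood and recomputes every
    measure in both its naive and weighted form, together with the mean
    error of 10-year absolute risks over the case-cohort set.
    """
    cfg = ctx.config
    stage = _full_stage_out if _full_stage_out is not None else _full_stage(ctx, seed)
    cohort = stage["cohort"]
    full = stage["full"]
    fit1 = stage["fit1"]
    risk1 = stage["risk1"]
    rec = {"fraction": fraction, **stage["record"]}
    design = (
        full
        if fraction == 1.0
        else draw_case_cohort(cohort, fraction, seed=stage["design_seed"])
    )
    members = design.member_indices()
    cfit1 = fit_weighted_cox(design, covariate_names=cfg.model1, scheme=cfg.scheme)
    cfit2 = fit_weighted_cox(design, covariate_names=cfg.model2, scheme=cfg.scheme)
    age_j = list(cfg.model1).index("age")
    age_j2 = list(cfg.model2).index("age")
    rec["cc_n"] = len(members)
    rec["full_beta_age"] = float(fit1.betas[age_j])
    rec["cc_beta_age"] = float(cfit1.betas[age_j])
    rec["cc_beta_age_se"] = float(cfit1.se_robust[age_j])
    rec["cc2_beta_age"] = float(cfit2.betas[age_j2])
    rec["cc2_beta_age_se"] = float(cfit2.se_robust[age_j2])
    clp1 = cfit1.linear_predictor(cohort.covariate_matrix(cfg.model1))
    for k, v in _metric_block(clp1, design, cfg.scheme, full=(fraction == 1.0)).items():
        rec[f"cc_{k}"] = v
    # weight-1 inclusion of non-subcohort cases at their own event keeps the
    # denominator positive at tiny fractions where the subcohort can be
    # momentarily empty late in follow-up
    cb1 = breslow_baseline(cfit1, design, include_nonsub_case_at_event=True)
    cb2 = breslow_baseline(cfit2, design, include_nonsub_case_at_event=True)
    crisk1 = predict_absolute_risk(
        cfit1, cb1, cohort.covariate_matrix(cfg.model1)[members], cfg.horizon
    )
    crisk2 = predict_absolute_risk(
        cfit2, cb2, cohort.covariate_matrix(cfg.model2)[members], cfg.horizon
    )
    celig = nri_eligibility(design, cfg.horizon)
    pos = np.full(len(cohort), -1, dtype=int)
    pos[members] = np.arange(len(members))
    rows = pos[celig.indices]
    for mode, key in (("categories", "cat"), ("continuous", "cont")):
        res = nri(crisk1[rows], crisk2[rows], celig, mode=mode, boundaries=cfg.categories)
        rec[f"cc_nri_{key}"] = res.nri
        rec[f"cc_nri_{key}_se"] = res.se_analytical
        rec[f"cc_nri_{key}_events"] = res.nri_events
        rec[f"cc_nri_{key}_nonevents"] = res.nri_nonevents
    rec["risk_err_mean"] = float(np.mean(crisk1 - risk1[members]))
    rec["converged_iters"] = int(cfit1.n_iter)
    logger.info(
        "replicate fraction=%.3g seed=%d cc_n=%d iters=%d",
        fraction, seed, len(members), cfit1.n_iter,
    )
    return rec


def run_sweep(config: SweepConfig, progress: bool = False) -> pd.DataFrame:
    """All replicates for all fractions; returns per-replicate records.

    The full-cohort stage of each replicate is shared across fractions (the
    gold standard depends on the outcome seed only, not on the design).
    """
    ctx = ScenarioContext.build(config)
    records = []
    for r in range(config.replicates):
        stage = _full_stage(ctx, seed=config.base_seed + r)
        for fraction in config.fractions:
            records.append(
                run_replicate(ctx, fraction, seed=config.base_seed + r, _full_stage_out=stage)
            )
        if progress and (r + 1) % 10 == 0:
            print(f"replicate {r + 1}/{config.replicates}")
    return pd.DataFrame.from_records(records)


def bias_percent(full_mean: float, case_cohort_mean: float) -> float:
    """Percent bias of a naive case-cohort mean against the full-cohort mean."""
    if full_mean == 0:
        raise ZeroDivisionError("bias percent undefined for a zero full-cohort mean")
    return 100.0 * (full_mean - case_cohort_mean) / full_mean


_METRICS = {
    "c": ("full_c_uw", "cc_c_uw", "cc_c_w", "full_c_uw_se", "cc_c_w_se"),
    "d": ("full_d_uw", "cc_d_uw", "cc_d_w", "full_d_uw_se", "cc_d_w_se"),
    "nri_cat": ("full_nri_cat", None, "cc_nri_cat", "full_nri_cat_se", "cc_nri_cat_se"),
    "nri_cont": ("full_nri_cont", None, "cc_nri_cont", "full_nri_cont_se", "cc_nri_cont_se"),
}


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Summarise replicate records per (fraction, metric).

    Columns: full-cohort mean; naive (unweighted) case-cohort mean with its
    percent bias; weighted mean; SE = mean analytical SE of the weighted
    estimate; ESE = SD of the weighted estimate over replicates; RE = ratio
    of mean analytical variances (full over case-cohort); ERE = the same
    ratio with empirical variances; and the mean 10-year absolute-risk
    error with its 5th-95th percentile band.  Needs at least two replicates
    per fraction.
    """
    if records.empty:
        raise ValueError("no replicate records to aggregate")
    rows = []
    for fraction, grp in records.groupby("fraction"):
        if len(grp) < 2:
            raise ValueError(f"need >= 2 replicates per fraction (fraction={fraction})")
        for metric, (full_col, uw_col, w_col, full_se_col, w_se_col) in _METRICS.items():
            full_mean = grp[full_col].mean()
            rows.append(
                {
                    "fraction": fraction,
                    "metric": metric,
                    "full_mean": full_mean,
                    "uw_mean": grp[uw_col].mean() if uw_col else np.nan,
                    "uw_bias_pct": (
                        bias_percent(full_mean, grp[uw_col].mean()) if uw_col else np.nan
                    ),
                    "w_mean": grp[w_col].mean(),
                    "se": grp[w_se_col].mean(),
                    "ese": grp[w_col].std(ddof=1),
                    "re": (grp[full_se_col] ** 2).mean() / (grp[w_se_col] ** 2).mean(),
                    "ere": grp[full_col].var(ddof=1) / grp[w_col].var(ddof=1)
                    if grp[w_col].var(ddof=1) > 0
                    else np.nan,
                    "risk_err_mean": grp["risk_err_mean"].mean(),
                    "risk_err_p5": grp["risk_err_mean"].quantile(0.05),
                    "risk_err_p95": grp["risk_err_mean"].quantile(0.95),
                }
            )
    return pd.DataFrame(rows)


def report(result: pd.DataFrame, outdir, formats: Sequence[str] = ("tables",)) -> list[Path]:
    """Write the aggregated sweep as delimited tables and figure data series.

    ``tables`` writes the results table; ``figures`` adds per-figure data
    (risk-error bands; C and D versus fraction; NRI versus fraction;
    relative efficiency versus fraction — empirical variances for the NRI);
    ``plots`` renders PNGs with matplotlib.
    """
    if result.empty:
        raise ValueError("empty sweep result")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.17g")
        written.append(path)

    save(result, "sweep_results.csv")
    if "figures" in formats or "plots" in formats:
        save(
            result[result.metric == "c"][
                ["fraction", "risk_err_mean", "risk_err_p5", "risk_err_p95"]
            ],
            "fig_risk_error.csv",
        )
        save(
            result[result.metric.isin(["c", "d"])][
                ["fraction", "metric", "full_mean", "uw_mean", "w_mean", "se", "ese"]
            ],
            "fig_discrimination.csv",
        )
        save(
            result[result.metric.str.startswith("nri")][
                ["fraction", "metric", "full_mean", "w_mean", "se", "ese"]
            ],
            "fig_nri.csv",
        )
        save(result[["fraction", "metric", "re", "ere"]], "fig_relative_efficiency.csv")
    if "plots" in formats:
        written += _render_plots(result, outdir)
    return written


def _render_plots(result: pd.DataFrame, outdir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    labels = {
        "c": "Harrell's C",
        "d": "Royston-Sauerbrei D",
        "nri_cat": "category NRI",
        "nri_cont": "continuous NRI",
    }
    for ax, metric in zip(axes.ravel(), labels):
        sub = result[result.metric == metric].sort_values("fraction")
        ax.plot(sub.fraction, sub.full_mean, "k--", label="full cohort")
        if sub.uw_mean.notna().any():
            ax.plot(sub.fraction, sub.uw_mean, "r-o", ms=3, label="unweighted")
        ax.plot(sub.fraction, sub.w_mean, "b-o", ms=3, label="weighted")
        ax.set_xlabel("subcohort sampling fraction")
        ax.set_title(labels[metric])
        ax.legend(fontsize=8)
    fig.tight_layout()
    p = outdir / "sweep_metrics.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(6, 4))
    for metric in labels:
        sub = result[result.metric == metric].sort_values("fraction")
        col = "ere" if metric.startswith("nri") else "re"
        ax.plot(sub.fraction, sub[col], "-o", ms=3, label=labels[metric])
    ax.axhline(1.0, color="grey", lw=0.5)
    ax.set_xlabel("subcohort sampling fraction")
    ax.set_ylabel("relative efficiency vs full cohort")
    ax.legend(fontsize=8)
    fig.tight_layout()
    p = outdir / "sweep_efficiency.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
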