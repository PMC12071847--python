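"""End-to-end pipeline: simulate (or load) → filter → fit → diagnose → report.

Every run writes a frozen copy of the resolved configuration and emits
machine-readable CSV/JSON artifacts plus a human-readable ``report.txt``.
Cohort descriptors in the report (patient count, CBCs per patient, median
continuous duration) are recomputed from the filtered data, never copied
from the configuration.  In simulation mode a recovery table juxtaposes the
generating truth with the posterior summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_io import EligibilityRules, PatientTimeline, apply_eligibility, read_cbc_table
from .core_model import mean_lifespan
from .diagnostics import (convergence_verdict, loo_khat, posterior_predictive,
                          rank_statistics)
from .inference import FitConfig, FitResult, build_model, fit, summarize
from .synthetic_cohort import (DAYS_PER_MONTH, Cohort, CohortConfig,
                               generate_cohort, write_cohort)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "timelines_from_records"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial artifacts are left for debugging."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run.

    Exactly one of ``cohort`` (simulation mode) or ``input_csv`` (data mode)
    must be set.  Eligibility thresholds default to the study rules
    (≥5 CBCs, baseline MCV ≤ 98 fL, 28-day baseline window, 30-day gap).
    """

    output_dir: str | Path = "rbclifespan_run"
    cohort: CohortConfig | None = field(default_factory=CohortConfig)
    input_csv: str | Path | None = None
    schema_config: dict | str | None = None
    dispensing_csv: str | Path | None = None
    eligibility: EligibilityRules = field(default_factory=EligibilityRules)
    fit: FitConfig = field(default_factory=FitConfig)
    ppc_replicates: int = 50
    make_plots: bool = True

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.input_csv is None):
            raise ValueError("set exactly one of cohort (simulate mode) or input_csv (data mode)")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(self.output_dir)
        if self.input_csv is not None:
            d["input_csv"] = str(self.input_csv)
        d["package_version"] = __version__
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        d.pop("package_version", None)
        if d.get("cohort") is not None:
            d["cohort"] = CohortConfig.from_yaml(yaml.safe_dump(d["cohort"]))
        if d.get("eligibility") is not None:
            d["eligibility"] = EligibilityRules(**d["eligibility"])
        if d.get("fit") is not None:
            d["fit"] = FitConfig(**d["fit"])
        return cls(**d)


def timelines_from_records(records: pd.DataFrame) -> list[PatientTimeline]:
    """Split a tidy record table into per-patient timelines (no dispensing
    info: the last CBC time stands in for the treatment-episode end)."""
    return [PatientTimeline(str(pid), grp.reset_index(drop=True))
            for pid, grp in records.groupby("patient_id", sort=True)]


def cohort_descriptors(timelines: list[PatientTimeline]) -> dict:
    """Descriptive statistics recomputed from the (filtered) data."""
    n_per = [len(tl.records) for tl in timelines]
    last_t = [float(tl.records["t_days"].max()) for tl in timelines]
    return {
        "n_patients": len(timelines),
        "n_cbc_total": int(np.sum(n_per)),
        "mean_cbc_per_patient": float(np.mean(n_per)),
        "median_duration_months": float(np.median(last_t) / DAYS_PER_MONTH),
    }


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                log.info("stage %s ...", name)
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(name, err) from err
        return wrapped
    return deco


@_stage("simulate")
def _stage_simulate(config: PipelineConfig, outdir: Path):
    cohort = generate_cohort(config.cohort)
    write_cohort(cohort, outdir / "cohort.csv", outdir / "truth.csv")
    return cohort


@_stage("load")
def _stage_load(config: PipelineConfig):
    return read_cbc_table(config.input_csv, config.schema_config, config.dispensing_csv)


@_stage("eligibility")
def _stage_eligibility(timelines, rules: EligibilityRules, outdir: Path):
    included, exclusions = apply_eligibility(timelines, rules)
    exclusions.to_csv(outdir / "exclusions.csv", index=False)
    if not included:
        raise ValueError("no eligible patients after filtering")
    return included, exclusions


@_stage("fit")
def _stage_fit(included, fit_config: FitConfig, outdir: Path) -> FitResult:
    model = build_model(included)
    result = fit(model, fit_config)
    summarize(result).to_csv(outdir / "summaries.csv")
    # pooled population-level draws in a flat columnar layout
    post = result.idata.posterior
    cols = {}
    for name in ("mu_survival", "sigma_survival", "lifespan_days",
                 "mcv_pre", "mcv_post", "mchc_pre", "mchc_post",
                 "rbc_pre", "rbc_post", "hgb_pre", "hgb_post"):
        cols[name] = post[name].values.ravel()
    pd.DataFrame(cols).to_csv(outdir / "draws_population.csv", index=False)
    return result


@_stage("diagnose")
def _stage_diagnose(result: FitResult, config: PipelineConfig, outdir: Path):
    loo = loo_khat(result)
    diag = result.diagnostics()
    diag.update({
        "elpd_loo": loo.elpd_estimate, "elpd_loo_se": loo.elpd_se,
        "n_khat_gt_0.7": loo.n_khat_gt_07, "n_khat_gt_1.0": loo.n_khat_gt_10,
        "step_sizes": result.step_sizes,
    })
    ranks = {}
    for par in ("lifespan_days", "mcv_pre", "mcv_post"):
        rr = rank_statistics(result, par)
        ranks[par] = {"chi2": rr.statistic.tolist(), "pvalue": rr.pvalue.tolist()}
    diag["rank_uniformity"] = ranks
    (outdir / "diagnostics.json").write_text(json.dumps(diag, indent=2))
    (outdir / "verdict.txt").write_text(convergence_verdict(result, loo) + "\n")
    if config.make_plots:
        _diagnostic_plots(result, loo, config, outdir)
    return loo, diag


def _diagnostic_plots(result: FitResult, loo, config: PipelineConfig, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 3.5))
    for ax, obs, label in zip(axes, ("mcv", "n_rbc", "mchc"),
                              ("MCV (fL)", "RBC count (10^12/L)", "MCHC (g/dL)")):
        ppc = posterior_predictive(result, obs, n_rep=config.ppc_replicates,
                                   seed=result.config.seed)
        ax.plot(ppc.grid, ppc.replicate_densities.T, color="C0", alpha=0.12, lw=0.7)
        ax.plot(ppc.grid, ppc.mean_density, "C1-.", lw=1.5, label="replicate mean")
        ax.plot(ppc.grid, ppc.observed_density, "k-", lw=1.5, label="observed")
        ax.set_xlabel(label)
        ax.legend(fontsize=8)
    fig.suptitle("Posterior predictive checks")
    fig.tight_layout()
    fig.savefig(outdir / "ppc.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(loo.pointwise_khat, ".", ms=3)
    for y, style in ((0.7, "--"), (1.0, ":")):
        ax.axhline(y, color="C0", ls=style, lw=1)
    ax.set_xlabel("blood draw")
    ax.set_ylabel("Pareto k-hat")
    fig.tight_layout()
    fig.savefig(outdir / "khat.png", dpi=120)
    plt.close(fig)


@_stage("report")
def _stage_report(result: FitResult, included, cohort: Cohort | None,
                  exclusions: pd.DataFrame, diag: dict, outdir: Path):
    desc = cohort_descriptors(included)
    summaries = summarize(result)
    recovery = None
    if cohort is not None:
        recovery = _recovery_table(result, cohort)
        recovery.to_csv(outdir / "recovery.csv")
    pd.DataFrame([desc]).to_csv(outdir / "descriptors.csv", index=False)
    lines = [
        f"rbclifespan {__version__} report",
        "=" * 34,
        "",
        "Cohort (recomputed from filtered data)",
        f"  patients included: {desc['n_patients']} (excluded: {len(exclusions)})",
        f"  CBC draws: {desc['n_cbc_total']} (mean {desc['mean_cbc_per_patient']:.1f}/patient)",
        f"  median continuous duration: {desc['median_duration_months']:.1f} months",
        "",
        "Posterior summaries (median [95% CdI])",
    ]
    for name, row in summaries.iterrows():
        lines.append(f"  {name:>20}: {row['median']:8.2f}  "
                     f"[{row['ci_2.5%']:.2f}, {row['ci_97.5%']:.2f}]")
    lines += ["", "Convergence",
              f"  divergences={diag['divergences']}  max R-hat={diag['max_rhat']:.4f}  "
              f"min bulk-ESS={diag['min_bulk_ess']:.0f}",
              f"  PSIS-LOO: elpd={diag['elpd_loo']:.1f} (se {diag['elpd_loo_se']:.1f}); "
              f"k-hat>0.7: {diag['n_khat_gt_0.7']}, k-hat>1.0: {diag['n_khat_gt_1.0']}"]
    if recovery is not None:
        lines += ["", "Recovery (generating truth vs posterior)"]
        for name, row in recovery.iterrows():
            ok = "inside" if row["covered"] else "OUTSIDE"
            lines.append(f"  {name:>20}: truth {row['truth']:8.2f} vs "
                         f"{row['median']:8.2f} [{row['ci_2.5%']:.2f}, {row['ci_97.5%']:.2f}] "
                         f"({ok} 95% CdI)")
    text = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(text)
    return desc, recovery, text


def _recovery_table(result: FitResult, cohort: Cohort) -> pd.DataFrame:
    pop = cohort.config.population
    truths = {
        "lifespan_days": mean_lifespan(cohort.config.survival),
        "mcv_pre": pop.mu_mcv_old, "mcv_post": pop.mu_mcv_new,
        "mcv_delta": pop.mu_mcv_new - pop.mu_mcv_old,
        "mchc_pre": pop.mu_mchc_old, "mchc_post": pop.mu_mchc_new,
        "mchc_delta": pop.mu_mchc_new - pop.mu_mchc_old,
        "rbc_pre": pop.mu_n_old, "rbc_post": pop.mu_n_new,
        "rbc_delta_decrease": pop.mu_n_old - pop.mu_n_new,
        "hgb_pre": pop.mu_n_old * pop.mu_mcv_old * pop.mu_mchc_old / 1000.0,
        "hgb_post": pop.mu_n_new * pop.mu_mcv_new * pop.mu_mchc_new / 1000.0,
    }
    truths["hgb_delta"] = truths["hgb_post"] - truths["hgb_pre"]
    summ = summarize(result)
    rows = []
    for name, truth in truths.items():
        row = summ.loc[name]
        rows.append({"quantity": name, "truth": truth, "median": row["median"],
                     "ci_2.5%": row["ci_2.5%"], "ci_97.5%": row["ci_97.5%"],
                     "covered": bool(row["ci_2.5%"] <= truth <= row["ci_97.5%"])})
    return pd.DataFrame(rows).set_index("quantity")


def run_pipeline(config: PipelineConfig, stop_after: str = "report") -> dict:
    """Execute the pipeline stages in order (simulate/load → eligibility →
    fit → diagnose → report), optionally stopping early; returns the report
    bundle as a dict (later-stage keys absent when stopped early)."""
    order = ["simulate", "eligibility", "fit", "diagnose", "report"]
    if stop_after not in order:
        raise ValueError(f"stop_after must be one of {order}")
    stop = order.index(stop_after)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(config.to_yaml())

    cohort = None
    if config.cohort is not None:
        cohort = _stage_simulate(config, outdir)
        timelines = timelines_from_records(cohort.records)
    else:
        timelines = _stage_load(config)
    if stop < 1:
        return {"output_dir": outdir, "cohort": cohort}
    included, exclusions = _stage_eligibility(timelines, config.eligibility, outdir)
    if stop < 2:
        return {"output_dir": outdir, "cohort": cohort, "included": included,
                "exclusions": exclusions}
    result = _stage_fit(included, config.fit, outdir)
    if stop < 3:
        return {"output_dir": outdir, "cohort": cohort, "included": included,
                "exclusions": exclusions, "fit": result, "summaries": summarize(result)}
    loo, diag = _stage_diagnose(result, config, outdir)
    if stop < 4:
        return {"output_dir": outdir, "cohort": cohort, "included": included,
                "exclusions": exclusions, "fit": result, "loo": loo,
                "diagnostics": diag, "summaries": summarize(result)}
    desc, recovery, text = _stage_report(result, included, cohort, exclusions, diag, outdir)
    return {
        "output_dir": outdir,
        "cohort": cohort,
        "included": included,
        "exclusions": exclusions,
        "fit": result,
        "loo": loo,
        "diagnostics": diag,
        "descriptors": desc,
        "summaries": summarize(result),
        "recovery": recovery,
        "report_text": text,
    }
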