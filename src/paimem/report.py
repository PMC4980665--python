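"""End-to-end pipeline: simulate -> fit networks -> fit Bayesian models -> report.

``run_pipeline`` produces a reproducible bundle directory:

- ``schedule.csv``, ``dataset.csv`` — the trial program and generated data
- ``model_comparison.csv`` — NLL / parameter count / BIC per network family
- ``predicted_profiles.csv`` — per-category predicted proportion correct for
  every fitted network, next to the empirical proportions
- ``posterior_accuracy.json``, ``posterior_rt.json``, ``posterior_logistic.json``
  — posterior summaries (mean, 95% HDI, rhat, ESS) and key contrasts
- ``run_log.json`` — config, stage seeds, row counts, wall times, versions

``render_report`` turns a bundle into ``report.md`` plus bar-chart figures
with HDI error bars (accuracy, RT, model profiles) and an odds-ratio plot.
Every number in the report is read from a bundle artifact; nothing is
recomputed at render time.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bayes.accuracy import fit_accuracy
from .bayes.logistic import fit_logistic
from .bayes.rt import fit_rt
from .bayes.sampler import MCMCConfig
from .data import write_dataset_csv
from .fitting import MODEL_FAMILIES, NetworkGridFit, predicted_profile
from .generate import default_config, generate
from .task import build_schedule, validate_schedule, write_schedule_csv

__all__ = ["RunConfig", "run_pipeline", "render_report"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    experiment_id: int = 1
    n_subjects: int | None = None  # default: the experiment's sample size
    seed: int = 0
    out_dir: str | Path = "paimem_run"
    mcmc_draws: int = 2000
    mcmc_chains: int = 4
    families: tuple = MODEL_FAMILIES
    grids: dict | None = None  # family -> grid; None: defaults
    generator_overrides: dict = field(default_factory=dict)
    verbosity: int = 0


def _stage_seed(base: int, index: int) -> int:
    # counter-based fan-out: reproducible, stage-independent
    return int((base * 7919 + 104729 * index) % (2**31 - 1))


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; partial outputs are preserved if a stage fails."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "config": {
            "experiment_id": config.experiment_id,
            "n_subjects": config.n_subjects,
            "seed": config.seed,
            "mcmc_draws": config.mcmc_draws,
            "mcmc_chains": config.mcmc_chains,
        },
        "stages": [],
    }
    bundle: dict = {"dir": out, "log": log}

    def stage(name, fn):
        t0 = time.time()
        result = fn()
        entry = {"stage": name, "seconds": round(time.time() - t0, 2)}
        log["stages"].append(entry)
        logger.info("stage %s done in %.1fs", name, entry["seconds"])
        (out / "run_log.json").write_text(json.dumps(log, indent=2))
        return result

    # 1. schedule
    def build():
        schedule = build_schedule(config.experiment_id, _stage_seed(config.seed, 0))
        violations = validate_schedule(schedule)
        if violations:
            raise RuntimeError(f"schedule violations: {violations[:3]}")
        write_schedule_csv(schedule, out / "schedule.csv")
        return schedule

    schedule = stage("schedule", build)
    bundle["schedule"] = schedule

    # 2. synthetic behavior
    def simulate():
        gen = default_config(
            config.experiment_id,
            n_subjects=config.n_subjects,
            seed=_stage_seed(config.seed, 1),
            **config.generator_overrides,
        )
        dataset = generate(gen, schedule)
        write_dataset_csv(dataset, out / "dataset.csv")
        log["n_rows_dataset"] = len(dataset)
        return dataset

    dataset = stage("simulate", simulate)
    bundle["dataset"] = dataset

    # 3. network model comparison
    def fit_networks():
        rows, profiles = [], []
        for family in config.families:
            grid = (config.grids or {}).get(family)
            fit = NetworkGridFit(family=family, grid=grid).fit(dataset)
            rows.append(fit.result_.as_dict())
            prof = fit.predicted_profile(schedule).as_frame()
            prof.insert(0, "model", family)
            profiles.append(prof)
        comparison = pd.DataFrame(
            [
                {
                    "model": r["model"],
                    "nll_per_participant": round(r["nll_per_participant"], 2),
                    "n_params": r["n_params"],
                    "bic_per_participant": round(r["bic_per_participant"], 2),
                    "best_params": json.dumps(r["params"]),
                }
                for r in rows
            ]
        )
        comparison.to_csv(out / "model_comparison.csv", index=False)
        empirical = (
            dataset.groupby(["phase", "relation"], observed=True)["correct"]
            .mean().rename("p_correct").reset_index()
        )
        empirical.insert(0, "model", "empirical")
        pd.concat(profiles + [empirical], ignore_index=True).to_csv(
            out / "predicted_profiles.csv", index=False
        )
        return comparison

    bundle["model_comparison"] = stage("fit_networks", fit_networks)

    # 4. hierarchical Bayesian analyses
    factor = config.experiment_id == 3
    mcmc = MCMCConfig(
        chains=config.mcmc_chains, draws=config.mcmc_draws,
        burn_in=max(500, config.mcmc_draws // 4),
        adapt_steps=max(300, config.mcmc_draws // 8),
    )

    def bayes_accuracy():
        model = fit_accuracy(
            dataset, mcmc.with_seed(_stage_seed(config.seed, 2)), factor=factor
        )
        payload = [s.as_dict() for s in model.summaries_.values()]
        for a, b in ((("source", "AB"), ("source", "BC")),
                     (("choice", "AB"), ("choice", "BC"))):
            if a in model.accuracy_draws_ and b in model.accuracy_draws_:
                payload.append(model.accuracy_contrast(a, b).as_dict())
        (out / "posterior_accuracy.json").write_text(json.dumps(payload, indent=2))
        return model

    stage("bayes_accuracy", bayes_accuracy)

    def bayes_rt():
        payload = []
        for phase in ("choice", "source"):
            model = fit_rt(
                dataset, mcmc.with_seed(_stage_seed(config.seed, 3)), phase=phase
            )
            payload.extend(s.as_dict() for s in model.summaries_.values())
            for a, b in (("AB", "BC"), ("AB", "AC"), ("BC", "AC")):
                if a in model.relations_ and b in model.relations_:
                    c = model.rt_contrast(a, b).as_dict()
                    c["name"] = f"rt_{phase}_{a}_minus_{b}"
                    payload.append(c)
        (out / "posterior_rt.json").write_text(json.dumps(payload, indent=2))

    stage("bayes_rt", bayes_rt)

    def bayes_logistic():
        if not any(c.relation == "AC" for c in schedule.choice_trials):
            (out / "posterior_logistic.json").write_text(json.dumps([]))
            return
        model = fit_logistic(
            dataset, mcmc.with_seed(_stage_seed(config.seed, 4)), factor=factor
        )
        payload = [s.as_dict() for s in model.summaries_.values()]
        payload.append(model.coefficient_contrast("ab_source", "bc_source").as_dict())
        (out / "posterior_logistic.json").write_text(json.dumps(payload, indent=2))

    stage("bayes_logistic", bayes_logistic)
    return bundle


# ---------------------------------------------------------------------------
# rendering

_SECTIONS = {
    "model_comparison.csv": "Model comparison (NLL/BIC per participant)",
    "predicted_profiles.csv": "Predicted vs. empirical accuracy profiles",
    "posterior_accuracy.json": "Accuracy posteriors",
    "posterior_rt.json": "Reaction-time posteriors (seconds)",
    "posterior_logistic.json": "Logistic regression of AC-choice correctness",
}


def render_report(bundle_dir: str | Path) -> Path:
    """Render ``report.md`` (+ figures) from the artifacts of one bundle.

    Missing artifacts are rendered as explicit gaps, never recomputed.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(bundle_dir)
    lines = ["# PAI analysis report", ""]
    for fname, title in _SECTIONS.items():
        path = out / fname
        lines.append(f"## {title}")
        if not path.exists():
            lines.append("_missing: artifact not produced_\n")
            continue
        if fname.endswith(".csv"):
            frame = pd.read_csv(path)
            lines.append(frame.to_markdown(index=False))
        else:
            payload = json.loads(path.read_text())
            frame = pd.DataFrame(payload)
            if frame.empty:
                lines.append("_empty section_\n")
                continue
            lines.append(frame.round(4).to_markdown(index=False))
        lines.append("")

    figures = []
    acc_path = out / "posterior_accuracy.json"
    if acc_path.exists():
        frame = pd.DataFrame(json.loads(acc_path.read_text()))
        acc = frame[frame["name"].str.startswith("accuracy_")]
        if not acc.empty:
            fig, ax = plt.subplots(figsize=(6, 3.2))
            xs = np.arange(len(acc))
            ax.bar(xs, acc["mean"], color="#4878b0")
            ax.errorbar(
                xs, acc["mean"],
                yerr=[acc["mean"] - acc["hdi_low"], acc["hdi_high"] - acc["mean"]],
                fmt="none", ecolor="k", capsize=3,
            )
            ax.set_xticks(xs)
            ax.set_xticklabels(
                [n.replace("accuracy_", "") for n in acc["name"]], rotation=30
            )
            ax.set_ylabel("proportion correct")
            ax.axhline(0.5, ls="--", c="grey", lw=0.8)
            fig.tight_layout()
            fig.savefig(out / "fig_accuracy.png", dpi=120)
            plt.close(fig)
            figures.append("fig_accuracy.png")
    rt_path = out / "posterior_rt.json"
    if rt_path.exists():
        frame = pd.DataFrame(json.loads(rt_path.read_text()))
        rt = frame[frame["name"].str.startswith("rt_seconds_choice")]
        if not rt.empty:
            fig, ax = plt.subplots(figsize=(5, 3.2))
            xs = np.arange(len(rt))
            ax.bar(xs, rt["mean"], color="#b04848")
            ax.errorbar(
                xs, rt["mean"],
                yerr=[rt["mean"] - rt["hdi_low"], rt["hdi_high"] - rt["mean"]],
                fmt="none", ecolor="k", capsize=3,
            )
            ax.set_xticks(xs)
            ax.set_xticklabels([n.rsplit("_", 1)[-1] for n in rt["name"]])
            ax.set_ylabel("choice RT (s)")
            fig.tight_layout()
            fig.savefig(out / "fig_rt.png", dpi=120)
            plt.close(fig)
            figures.append("fig_rt.png")
    prof_path = out / "predicted_profiles.csv"
    if prof_path.exists():
        frame = pd.read_csv(prof_path)
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.2), sharey=True)
        for ax, phase in zip(axes, ("choice", "source")):
            sub = frame[frame["phase"] == phase]
            for model, grp in sub.groupby("model"):
                grp = grp.set_index("relation").reindex(["AB", "BC", "AC"])
                marker = "o" if model == "empirical" else "."
                lw = 2.0 if model == "empirical" else 1.0
                ax.plot(grp.index, grp["p_correct"], marker=marker, lw=lw, label=model)
            ax.set_title(f"{phase} trials")
            ax.axhline(0.5, ls="--", c="grey", lw=0.8)
        axes[0].set_ylabel("proportion correct")
        axes[1].legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "fig_profiles.png", dpi=120)
        plt.close(fig)
        figures.append("fig_profiles.png")
    logit_path = out / "posterior_logistic.json"
    if logit_path.exists():
        frame = pd.DataFrame(json.loads(logit_path.read_text()))
        if not frame.empty:
            ors = frame[frame["name"].str.startswith("odds_ratio_")]
            if not ors.empty:
                fig, ax = plt.subplots(figsize=(5, 3.2))
                ys = np.arange(len(ors))
                ax.errorbar(
                    ors["mean"], ys,
                    xerr=[ors["mean"] - ors["hdi_low"], ors["hdi_high"] - ors["mean"]],
                    fmt="o", capsize=3,
                )
                ax.set_yticks(ys)
                ax.set_yticklabels([n.replace("odds_ratio_", "") for n in ors["name"]])
                ax.axvline(1.0, ls="--", c="grey", lw=0.8)
                ax.set_xlabel("odds ratio")
                fig.tight_layout()
                fig.savefig(out / "fig_odds_ratios.png", dpi=120)
                plt.close(fig)
                figures.append("fig_odds_ratios.png")

    if figures:
        lines.append("## Figures")
        lines.extend(f"![{f}]({f})" for f in figures)
        lines.append("")
    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report
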