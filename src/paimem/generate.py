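"""Synthetic subject data with the statistical structure of the PAI studies.

The generator emulates, per experiment variant, the group-level behavioral
profile the analyses assume:

- per-subject, per-category accuracy heterogeneity: subject rates drawn from
  Beta distributions parameterized by mode ``omega`` and concentration
  ``kappa``, with default modes set to the reported group summaries of each
  experiment (e.g. experiment 1: AB choice 0.93, AB source 0.83, BC source
  0.57 — the pronounced AB >> BC source asymmetry);
- logistic dependence of AC-choice correctness on AB/BC/AC source and BC
  choice correctness for the same triplet, plus a Gaussian subject effect,
  with a calibrated intercept so the marginal AC accuracy hits its mode;
- heavy-tailed log reaction times (Student-t), ordered AB < BC < AC, with a
  per-subject shift, truncated at the response cap;
- experiment 3's novel/familiar scene factor, null by default, and
  independent Bernoulli scene recognition (so subsequent-memory splits are
  null by construction).

AB/BC choice and all source correctness are independent across triplets given
the subject-level rates; correlation enters only through the AC logistic
model — exactly the dependence the hierarchical regression estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .bayes.beta import beta_from_mode
from .data import DATASET_COLUMNS
from .task import ExperimentSchedule, build_schedule

__all__ = [
    "LogisticCoeffs",
    "GeneratorConfig",
    "GeneratorTruth",
    "default_config",
    "generate",
    "calibrate_intercept",
    "corrected_hit_rate",
    "EXPERIMENT_DEFAULTS",
]

#: categories whose per-subject rates are beta-distributed (AC choice is
#: produced by the logistic model instead)
BETA_CATEGORIES = [
    ("choice", "AB"),
    ("choice", "BC"),
    ("source", "AB"),
    ("source", "BC"),
    ("source", "AC"),
]

ALL_CATEGORIES = [("choice", "AB"), ("choice", "BC"), ("choice", "AC")] + [
    ("source", r) for r in ("AB", "BC", "AC")
]


@dataclass(frozen=True)
class LogisticCoeffs:
    """Coefficients of the AC-choice generative logistic model (log-odds)."""

    beta_ab_source: float
    beta_bc_source: float
    beta_ac_source: float
    beta_bc_choice: float
    subject_sd: float
    beta0: float | None = None  # None: calibrated to the AC-choice mode


def _log(x: float) -> float:
    return float(np.log(x))


# Reported group summaries per experiment, used as generator truth.  Choice-RT
# means are the published seconds; source-RT locations are anchored to the
# published AB-vs-BC/AC contrasts (absolute source RTs were not reported).
# The AC-source regression coefficient was not reported and defaults to 0.
EXPERIMENT_DEFAULTS: dict[int, dict] = {
    1: dict(
        n_subjects=24,
        accuracy_modes={
            ("choice", "AB"): 0.93, ("choice", "BC"): 0.89, ("choice", "AC"): 0.83,
            ("source", "AB"): 0.83, ("source", "BC"): 0.57, ("source", "AC"): 0.69,
        },
        rt_location={
            ("choice", "AB"): _log(2.80), ("choice", "BC"): _log(3.55),
            ("choice", "AC"): _log(4.70),
            ("source", "AB"): _log(1.50), ("source", "BC"): _log(1.65),
            ("source", "AC"): _log(1.58),
        },
        logistic=LogisticCoeffs(0.66, 0.70, 0.0, 0.72, subject_sd=0.5),
    ),
    2: dict(
        n_subjects=21,
        accuracy_modes={
            ("choice", "AB"): 0.89, ("choice", "BC"): 0.80, ("choice", "AC"): 0.66,
            ("source", "AB"): 0.72, ("source", "BC"): 0.50, ("source", "AC"): 0.54,
        },
        rt_location={
            ("choice", "AB"): _log(1.91), ("choice", "BC"): _log(2.16),
            ("choice", "AC"): _log(2.62),
            ("source", "AB"): _log(1.20), ("source", "BC"): _log(1.25),
            ("source", "AC"): _log(1.28),
        },
        logistic=LogisticCoeffs(0.59, 0.42, 0.0, 0.46, subject_sd=0.5),
    ),
    3: dict(
        n_subjects=16,
        accuracy_modes={
            ("choice", "AB"): 0.91, ("choice", "BC"): 0.88, ("choice", "AC"): 0.80,
            ("source", "AB"): 0.79, ("source", "BC"): 0.59, ("source", "AC"): 0.69,
        },
        rt_location={
            ("choice", "AB"): _log(2.17), ("choice", "BC"): _log(2.43),
            ("choice", "AC"): _log(2.93),
            ("source", "AB"): _log(1.30), ("source", "BC"): _log(1.44),
            ("source", "AC"): _log(1.62),
        },
        logistic=LogisticCoeffs(0.76, 0.49, 0.0, 0.67, subject_sd=0.5),
    ),
}
EXPERIMENT_DEFAULTS[4] = {  # no separate summaries reported; experiment-1 profile
    **EXPERIMENT_DEFAULTS[1],
    "n_subjects": 16,
}


@dataclass(frozen=True)
class GeneratorConfig:
    experiment_id: int
    n_subjects: int
    accuracy_modes: dict[tuple[str, str], float]
    logistic_coeffs: LogisticCoeffs
    rt_location: dict[tuple[str, str], float]  # mean log-seconds
    concentration: float = 50.0  # kappa; between-subject spread of accuracies
    rt_scale: dict[tuple[str, str], float] | float = 0.35  # log-scale sigma_j
    rt_df: float = 5.0  # Student-t normality parameter nu
    rt_subject_sd: float = 0.15  # per-subject shift of log-RT locations
    timeout_rate: float = 0.0
    novelty_effect: float = 0.0  # log-odds shift for novel-scene triplets
    scene_hit_rate: float = 0.45
    scene_fa_rate: float = 0.16
    seed: int = 0

    def __post_init__(self):
        if self.concentration <= 2.0:
            raise ValueError("concentration kappa must be > 2")
        if not 0.0 <= self.timeout_rate < 1.0:
            raise ValueError("timeout_rate must lie in [0, 1)")

    def rt_scale_of(self, cat: tuple[str, str]) -> float:
        if isinstance(self.rt_scale, dict):
            return self.rt_scale[cat]
        return float(self.rt_scale)


@dataclass
class GeneratorTruth:
    """Latent quantities behind one generated dataset (for recovery checks)."""

    subject_rates: pd.DataFrame  # subject, phase, relation, p
    subject_logit_bias: np.ndarray  # b_s of the AC logistic model
    subject_rt_shift: np.ndarray
    beta0: float
    scene_recognition: pd.DataFrame | None = None  # per-subject hit/miss/fa/cr


def default_config(experiment_id: int, n_subjects: int | None = None,
                   seed: int = 0, **overrides) -> GeneratorConfig:
    """Config whose defaults are each experiment's reported group summaries."""
    if experiment_id not in EXPERIMENT_DEFAULTS:
        raise ValueError(f"unknown experiment_id {experiment_id!r}")
    d = EXPERIMENT_DEFAULTS[experiment_id]
    cfg = GeneratorConfig(
        experiment_id=experiment_id,
        n_subjects=n_subjects if n_subjects is not None else d["n_subjects"],
        accuracy_modes=dict(d["accuracy_modes"]),
        logistic_coeffs=d["logistic"],
        rt_location=dict(d["rt_location"]),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# intercept calibration

def calibrate_intercept(config: GeneratorConfig, n_draws: int = 200_000,
                        tol: float = 0.005) -> float:
    """Intercept beta0 such that the marginal AC-choice accuracy matches its
    configured mode, integrating over the indicator distributions and the
    subject effect by Monte Carlo."""
    target = config.accuracy_modes[("choice", "AC")]
    rng = np.random.default_rng(config.seed + 104729)  # fixed offset stream
    kappa = config.concentration
    coeffs = config.logistic_coeffs
    predictors = [
        ("source", "AB"), ("source", "BC"), ("source", "AC"), ("choice", "BC"),
    ]
    betas = np.array([
        coeffs.beta_ab_source, coeffs.beta_bc_source,
        coeffs.beta_ac_source, coeffs.beta_bc_choice,
    ])
    x = np.empty((n_draws, 4))
    for k, cat in enumerate(predictors):
        a, b = beta_from_mode(config.accuracy_modes[cat], kappa)
        p = rng.beta(a, b, size=n_draws)
        x[:, k] = rng.random(n_draws) < p
    b_s = rng.normal(0.0, coeffs.subject_sd, size=n_draws)
    eta = x @ betas + b_s

    def marginal_error(beta0: float) -> float:
        return float(np.mean(expit(beta0 + eta))) - target

    lo, hi = -20.0, 20.0
    if marginal_error(lo) > 0 or marginal_error(hi) < 0:
        raise ValueError(
            "marginal AC accuracy unattainable: coefficients too extreme for "
            f"target {target}"
        )
    beta0 = float(brentq(marginal_error, lo, hi, xtol=1e-6))
    if abs(marginal_error(beta0)) > tol:
        raise ValueError("intercept calibration did not reach the target marginal")
    return beta0


# ---------------------------------------------------------------------------
# generation

def generate(
    config: GeneratorConfig,
    schedule: ExperimentSchedule | None = None,
    return_truth: bool = False,
):
    """Generate a trial-level behavioral dataset for one experiment.

    Deterministic under ``config.seed``: identical config and schedule yield a
    byte-identical CSV.
    """
    if schedule is None:
        schedule = build_schedule(config.experiment_id, seed=config.seed)
    if schedule.experiment_id != config.experiment_id:
        raise ValueError(
            f"config is for experiment {config.experiment_id} but schedule is "
            f"for experiment {schedule.experiment_id}"
        )
    rng = np.random.default_rng(config.seed)
    kappa = config.concentration
    coeffs = config.logistic_coeffs
    beta0 = coeffs.beta0 if coeffs.beta0 is not None else calibrate_intercept(config)
    cap = schedule.response_cap_seconds

    scene_of_triplet: dict[int, str] = {}
    if config.experiment_id == 3:
        for e in schedule.encoding_trials:
            if e.pair_kind == "BC" and e.preceding_scene is not None:
                scene_of_triplet[e.triplet_id] = e.preceding_scene

    # trial program, in presentation order
    choice_trials = sorted(
        schedule.choice_trials, key=lambda c: (c.session, c.order_index)
    )
    tids = sorted({c.triplet_id for c in choice_trials})
    tid_index = {tid: i for i, tid in enumerate(tids)}
    n_trials = len(choice_trials)
    trial_rel = np.array([c.relation for c in choice_trials])
    trial_tid = np.array([c.triplet_id for c in choice_trials])
    trial_sess = np.array([c.session for c in choice_trials])
    trial_idx = np.array([tid_index[c.triplet_id] for c in choice_trials])
    trial_cond = np.array(
        [scene_of_triplet.get(c.triplet_id, "") for c in choice_trials], dtype=object
    )
    novel_triplet = np.array(
        [scene_of_triplet.get(t) == "novel" for t in tids]
    )
    rel_mask = {rel: trial_rel == rel for rel in ("AB", "BC", "AC")}
    mu_choice = np.array(
        [config.rt_location[("choice", r)] for r in trial_rel]
    )
    mu_source = np.array(
        [config.rt_location[("source", r)] for r in trial_rel]
    )
    sg_choice = np.array([config.rt_scale_of(("choice", r)) for r in trial_rel])
    sg_source = np.array([config.rt_scale_of(("source", r)) for r in trial_rel])
    betas = np.array([
        coeffs.beta_ab_source, coeffs.beta_bc_source,
        coeffs.beta_ac_source, coeffs.beta_bc_choice,
    ])

    chunks: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    subject_bias = np.empty(config.n_subjects)
    subject_shift = np.empty(config.n_subjects)

    for si in range(config.n_subjects):
        subject = si + 1
        # subject-level latent rates; the novelty factor shifts the log-odds
        # of novel-scene triplets (null at the default of 0)
        p_cat: dict[tuple[str, str], np.ndarray] = {}
        for cat in BETA_CATEGORIES:
            a, b = beta_from_mode(config.accuracy_modes[cat], kappa)
            p = float(rng.beta(a, b))
            per_triplet = np.full(len(tids), p)
            if config.novelty_effect != 0.0 and scene_of_triplet:
                per_triplet = expit(
                    logit(per_triplet) + config.novelty_effect * novel_triplet
                )
            p_cat[cat] = per_triplet
            truth_rows.append(
                dict(subject=subject, phase=cat[0], relation=cat[1], p=p)
            )
        b_s = float(rng.normal(0.0, coeffs.subject_sd))
        shift = float(rng.normal(0.0, config.rt_subject_sd))
        subject_bias[si] = b_s
        subject_shift[si] = shift

        # correctness per triplet; AC choice depends on the other indicators
        correct: dict[tuple[str, str], np.ndarray] = {
            cat: rng.random(len(tids)) < p_cat[cat] for cat in BETA_CATEGORIES
        }
        x = np.column_stack(
            [
                correct[("source", "AB")],
                correct[("source", "BC")],
                correct[("source", "AC")],
                correct[("choice", "BC")],
            ]
        ).astype(float)
        p_ac = expit(beta0 + x @ betas + b_s)
        correct[("choice", "AC")] = rng.random(len(tids)) < p_ac

        ok_choice = np.empty(n_trials, dtype=bool)
        ok_source = np.empty(n_trials, dtype=bool)
        for rel, mask in rel_mask.items():
            ok_choice[mask] = correct[("choice", rel)][trial_idx[mask]]
            ok_source[mask] = correct[("source", rel)][trial_idx[mask]]

        rt_choice = _draw_rts(rng, mu_choice + shift, sg_choice, config.rt_df, cap)
        rt_source = _draw_rts(rng, mu_source + shift, sg_source, config.rt_df, cap)
        timeout_choice = rng.random(n_trials) < config.timeout_rate
        timeout_source = timeout_choice | (rng.random(n_trials) < config.timeout_rate)

        recognized_triplet = rng.random(len(tids)) < config.scene_hit_rate
        trial_recognized = np.where(
            np.asarray(trial_cond == "novel"),
            recognized_triplet[trial_idx],
            None,
        )

        is_ac = rel_mask["AC"]
        source_resp = np.where(
            ok_source,
            np.where(is_ac, "indirect", "direct"),
            np.where(is_ac, "direct", "indirect"),
        )
        choice_resp = np.where(ok_choice, "target", "foil")

        def interleave(a_choice, a_source, dtype=object):
            out = np.empty(2 * n_trials, dtype=dtype)
            out[0::2], out[1::2] = a_choice, a_source
            return out

        chunk = pd.DataFrame(
            {
                "subject": np.full(2 * n_trials, subject),
                "experiment": np.full(2 * n_trials, config.experiment_id),
                "session": interleave(trial_sess, trial_sess, dtype=int),
                "phase": interleave(
                    np.full(n_trials, "choice"), np.full(n_trials, "source")
                ),
                "relation": interleave(trial_rel, trial_rel),
                "triplet_id": interleave(trial_tid, trial_tid, dtype=int),
                "response": interleave(
                    np.where(timeout_choice, "", choice_resp),
                    np.where(timeout_source, "", source_resp),
                ),
                "correct": interleave(
                    ok_choice & ~timeout_choice,
                    ok_source & ~timeout_source,
                    dtype=bool,
                ),
                "rt_seconds": interleave(
                    np.where(timeout_choice, np.nan, rt_choice),
                    np.where(timeout_source, np.nan, rt_source),
                    dtype=float,
                ),
                "scene_condition": interleave(trial_cond, trial_cond),
                "scene_recognized": interleave(trial_recognized, trial_recognized),
            }
        )
        chunks.append(chunk)

    dataset = pd.concat(chunks, ignore_index=True).reindex(columns=DATASET_COLUMNS)
    if not return_truth:
        return dataset

    scene_rec = None
    if config.experiment_id == 3:
        rec_rows = []
        rec_rng = np.random.default_rng(config.seed + 15485863)
        n_old, n_foil = len(schedule.novel_scenes), len(schedule.foil_scenes)
        for si in range(config.n_subjects):
            hits = int(rec_rng.binomial(n_old, config.scene_hit_rate))
            fas = int(rec_rng.binomial(n_foil, config.scene_fa_rate))
            rec_rows.append(
                dict(
                    subject=si + 1, hits=hits, misses=n_old - hits,
                    false_alarms=fas, correct_rejections=n_foil - fas,
                )
            )
        scene_rec = pd.DataFrame(rec_rows)
    truth = GeneratorTruth(
        subject_rates=pd.DataFrame(truth_rows),
        subject_logit_bias=subject_bias,
        subject_rt_shift=subject_shift,
        beta0=beta0,
        scene_recognition=scene_rec,
    )
    return dataset, truth


def _draw_rts(rng, mu: np.ndarray, sigma: np.ndarray, df: float,
              cap: float) -> np.ndarray:
    """Log-RTs from shifted, scaled Student-t draws, truncated at the cap by
    redrawing (vectorized rejection)."""
    rt = np.exp(mu + sigma * rng.standard_t(df, size=mu.shape))
    for _ in range(1000):
        over = rt > cap
        if not over.any():
            return rt
        rt[over] = np.exp(mu[over] + sigma[over] * rng.standard_t(df, size=int(over.sum())))
    rt[rt > cap] = cap  # unreachable for any sane location/cap combination
    return rt


def corrected_hit_rate(hits: int, misses: int, false_alarms: int,
                       correct_rejections: int) -> float:
    """Recognition sensitivity: hit rate minus false-alarm rate."""
    for n in (hits, misses, false_alarms, correct_rejections):
        if n < 0:
            raise ValueError("counts must be nonnegative")
    if hits + misses == 0:
        raise ValueError("no old items: hit rate undefined")
    if false_alarms + correct_rejections == 0:
        raise ValueError("no foil items: false-alarm rate undefined")
    return hits / (hits + misses) - false_alarms / (false_alarms + correct_rejections)
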