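"""Synthetic behavior generator: distributional contracts and determinism."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paimem.bayes.beta import beta_from_mode
from paimem.data import (
    drop_timeouts,
    exclude_source_trials,
    write_dataset_csv,
)
from paimem.generate import (
    EXPERIMENT_DEFAULTS,
    GeneratorConfig,
    calibrate_intercept,
    corrected_hit_rate,
    default_config,
    generate,
)
from paimem.task import build_schedule


def csv_bytes(dataset):
    buf = io.StringIO()
    write_dataset_csv(dataset, buf)
    return buf.getvalue().encode()


def test_full_pipeline_determinism():
    a = generate(default_config(1, seed=11))
    b = generate(default_config(1, seed=11))
    assert csv_bytes(a) == csv_bytes(b)
    c = generate(default_config(1, seed=12))
    assert csv_bytes(a) != csv_bytes(c)


def test_rejects_bad_concentration():
    with pytest.raises(ValueError, match="kappa"):
        default_config(1, concentration=2.0)


def test_rejects_mismatched_schedule():
    schedule = build_schedule(2, seed=0)
    with pytest.raises(ValueError, match="experiment"):
        generate(default_config(1, seed=0), schedule)


def test_pooled_accuracy_near_configured_level():
    """Law of large numbers: pooled accuracy converges to the mean of the
    subject-rate distribution, Beta(mode omega, kappa)."""
    config = default_config(1, n_subjects=200, seed=11)
    dataset = generate(config)
    pooled = dataset[(dataset.phase == "choice") & (dataset.relation == "AB")][
        "correct"
    ].mean()
    a, b = beta_from_mode(0.93, config.concentration)
    expected = a / (a + b)
    assert pooled == pytest.approx(expected, abs=0.01)
    assert pooled == pytest.approx(0.93, abs=0.02)


def test_degenerate_modes_give_all_correct():
    config = default_config(
        1, n_subjects=5, seed=2,
        accuracy_modes={k: 0.999999 for k in EXPERIMENT_DEFAULTS[1]["accuracy_modes"]},
        concentration=1e7,
    )
    dataset = generate(config)
    non_ac = dataset[~((dataset.phase == "choice") & (dataset.relation == "AC"))]
    assert non_ac["correct"].mean() > 0.999


def test_subject_rates_follow_configured_beta():
    """Latent per-subject rates pass a KS test against Beta(omega, kappa)."""
    config = default_config(1, n_subjects=2000, seed=4)
    _, truth = generate(config, return_truth=True)
    rates = truth.subject_rates
    for (phase, relation), omega in (
        (("choice", "AB"), 0.93), (("source", "BC"), 0.57),
    ):
        p = rates[(rates.phase == phase) & (rates.relation == relation)]["p"]
        a, b = beta_from_mode(omega, config.concentration)
        stat, pval = stats.kstest(p, "beta", args=(a, b))
        assert pval > 0.01


def test_exclusion_rule_realism():
    """Applying the exclusion rule retains exactly the source rows whose
    parent choice was answered correctly (brute-force cross-check)."""
    dataset = generate(default_config(1, seed=6))
    kept = exclude_source_trials(dataset)
    kept_src = kept[kept.phase == "source"]
    choice = dataset[dataset.phase == "choice"].set_index(
        ["subject", "session", "triplet_id", "relation"]
    )["correct"]
    for row in kept_src.sample(200, random_state=0).itertuples():
        assert choice.loc[(row.subject, row.session, row.triplet_id, row.relation)]
    n_expected = sum(
        choice.loc[(r.subject, r.session, r.triplet_id, r.relation)]
        for r in dataset[dataset.phase == "source"].itertuples()
    )
    assert len(kept_src) == n_expected


def test_rt_ordering_and_caps():
    dataset = generate(default_config(1, n_subjects=50, seed=8))
    choice = dataset[dataset.phase == "choice"]
    means = choice.groupby("relation")["rt_seconds"].mean()
    assert means["AB"] < means["BC"] < means["AC"]
    assert dataset["rt_seconds"].max() <= 10.0
    exp2 = generate(default_config(2, n_subjects=10, seed=8))
    assert exp2["rt_seconds"].max() <= 5.0


def test_timeouts_marked_and_inherited():
    config = default_config(1, n_subjects=20, seed=9, timeout_rate=0.1)
    dataset = generate(config)
    timeouts = dataset[dataset.response == ""]
    assert 0.05 < len(timeouts) / len(dataset) < 0.25
    assert timeouts["rt_seconds"].isna().all()
    assert not timeouts["correct"].any()
    # a timed-out choice implies a timed-out source for the same probe
    t_choice = timeouts[timeouts.phase == "choice"].set_index(
        ["subject", "triplet_id", "relation"]
    ).index
    src = dataset[dataset.phase == "source"].set_index(
        ["subject", "triplet_id", "relation"]
    )
    assert (src.loc[t_choice, "response"] == "").all()
    assert len(drop_timeouts(dataset)) == len(dataset) - len(timeouts)


def test_ac_choice_depends_on_indicators():
    """The generative logistic coupling is recoverable by a plain maximum-
    likelihood logit fit on the indicator table (independent oracle)."""
    import statsmodels.api as sm

    from paimem.bayes.logistic import ac_regression_table

    config = default_config(1, n_subjects=500, seed=13)
    dataset = generate(config)
    table = ac_regression_table(dataset)
    X = sm.add_constant(table[["ab_source", "bc_source", "ac_source", "bc_choice"]])
    fit = sm.Logit(table["y"], X).fit(disp=0)
    assert fit.params["ab_source"] == pytest.approx(0.66, abs=0.1)
    assert fit.params["bc_source"] == pytest.approx(0.70, abs=0.1)
    assert fit.params["bc_choice"] == pytest.approx(0.72, abs=0.1)
    assert fit.params["ac_source"] == pytest.approx(0.0, abs=0.1)


def test_marginal_ac_accuracy_matches_mode():
    dataset = generate(default_config(1, n_subjects=500, seed=14))
    ac = dataset[(dataset.phase == "choice") & (dataset.relation == "AC")]
    assert ac["correct"].mean() == pytest.approx(0.83, abs=0.01)


def test_experiment3_scene_structure():
    config = default_config(3, seed=15)
    dataset, truth = generate(config, return_truth=True)
    # every triplet's BC study trial carries a scene, so every test trial
    # inherits a condition
    assert set(dataset["scene_condition"].unique()) == {"novel", "familiar"}
    novel = dataset[dataset.scene_condition == "novel"]
    assert novel["scene_recognized"].notna().all()
    # null subsequent-memory effect by construction
    split = novel.groupby("scene_recognized", observed=True)["correct"].mean()
    assert abs(split.diff().iloc[-1]) < 0.05
    assert truth.scene_recognition is not None
    rec = truth.scene_recognition.iloc[0]
    assert rec.hits + rec.misses == 40
    assert rec.false_alarms + rec.correct_rejections == 20


# -- intercept calibration --------------------------------------------------

def zero_coeff_config(target):
    from paimem.generate import LogisticCoeffs

    modes = dict(EXPERIMENT_DEFAULTS[1]["accuracy_modes"])
    modes[("choice", "AC")] = target
    return default_config(
        1, seed=3, accuracy_modes=modes,
        logistic_coeffs=LogisticCoeffs(0, 0, 0, 0, subject_sd=0.0),
    )


def test_calibrate_intercept_closed_forms():
    assert calibrate_intercept(zero_coeff_config(0.5)) == pytest.approx(0.0, abs=1e-4)
    assert calibrate_intercept(zero_coeff_config(0.83)) == pytest.approx(
        math.log(0.83 / 0.17), abs=1e-4
    )


def test_calibrate_intercept_monte_carlo_oracle():
    """With nonzero coefficients the calibrated marginal passes an
    independent large-sample simulation check."""
    config = default_config(1, seed=21)
    beta0 = calibrate_intercept(config)
    rng = np.random.default_rng(99)
    n = 1_000_000
    coeffs = config.logistic_coeffs
    x = np.empty((n, 4))
    for k, cat in enumerate(
        [("source", "AB"), ("source", "BC"), ("source", "AC"), ("choice", "BC")]
    ):
        a, b = beta_from_mode(config.accuracy_modes[cat], config.concentration)
        x[:, k] = rng.random(n) < rng.beta(a, b, size=n)
    eta = (
        beta0
        + x @ np.array([coeffs.beta_ab_source, coeffs.beta_bc_source,
                        coeffs.beta_ac_source, coeffs.beta_bc_choice])
        + rng.normal(0, coeffs.subject_sd, n)
    )
    marginal = (rng.random(n) < 1 / (1 + np.exp(-eta))).mean()
    assert marginal == pytest.approx(0.83, abs=0.006)


def test_corrected_hit_rate():
    assert corrected_hit_rate(10, 10, 0, 20) == pytest.approx(0.5)
    assert corrected_hit_rate(20, 0, 20, 0) == pytest.approx(0.0)
    # the reported 29% scale: 45% hits, 16% false alarms
    assert corrected_hit_rate(45, 55, 16, 84) == pytest.approx(0.29)
    with pytest.raises(ValueError):
        corrected_hit_rate(0, 0, 1, 1)
    with pytest.raises(ValueError):
        corrected_hit_rate(1, 1, 0, 0)
    with pytest.raises(ValueError):
        corrected_hit_rate(-1, 1, 1, 1)
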