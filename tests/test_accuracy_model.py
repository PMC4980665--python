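"""Hierarchical accuracy model: recovery, conjugacy, exclusion, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paimem.bayes.accuracy import AccuracyModel, accuracy_counts, fit_accuracy
from paimem.bayes.beta import beta_from_mode
from paimem.bayes.sampler import MCMCConfig
from paimem.data import DATASET_COLUMNS, exclude_source_trials
from paimem.generate import default_config, generate

from conftest import SMALL_MCMC


def make_binomial_dataset(p_by_subject, n_trials, seed=0, phase="choice",
                          relation="AB"):
    """Minimal one-category dataset with known per-subject rates."""
    rng = np.random.default_rng(seed)
    rows = []
    for s, p in enumerate(p_by_subject, start=1):
        correct = rng.random(n_trials) < p
        for t, ok in enumerate(correct, start=1):
            rows.append(
                dict(
                    subject=s, experiment=1, session=1, phase=phase,
                    relation=relation, triplet_id=t,
                    response="target" if ok else "foil", correct=bool(ok),
                    rt_seconds=1.0, scene_condition="", scene_recognized=pd.NA,
                )
            )
    return pd.DataFrame(rows, columns=DATASET_COLUMNS)


# -- data preparation -------------------------------------------------------

def test_accuracy_counts_apply_exclusion(exp1_data):
    _, dataset, _ = exp1_data
    counts = accuracy_counts(dataset)
    # choice totals are the full schedule; source totals only correct parents
    choice_ab = counts[(counts.phase == "choice") & (counts.relation == "AB")]
    assert (choice_ab["n"] == 80).all()
    src_ab = counts[(counts.phase == "source") & (counts.relation == "AB")]
    kept = exclude_source_trials(dataset)
    expected = (
        kept[(kept.phase == "source") & (kept.relation == "AB")]
        .groupby("subject").size()
    )
    assert (src_ab.set_index("subject")["n"] == expected).all()


def test_beta_from_mode_closed_forms():
    assert beta_from_mode(0.5, 4.0) == (2.0, 2.0)
    a, b = beta_from_mode(0.8, 12.0)
    assert a == pytest.approx(9.0, abs=1e-12)
    assert b == pytest.approx(3.0, abs=1e-12)
    a, b = beta_from_mode(0.5, 2.0 + 1e-9)
    assert a == pytest.approx(1.0, abs=1e-8)
    assert b == pytest.approx(1.0, abs=1e-8)
    with pytest.raises(ValueError):
        beta_from_mode(0.5, 2.0)
    with pytest.raises(ValueError):
        beta_from_mode(1.5, 10.0)


# -- recovery on the shared experiment-1 fit --------------------------------

def test_recovers_experiment1_category_accuracies(exp1_accuracy_fit, exp1_data):
    """Posterior mean accuracies land near the generating levels."""
    _, _, truth = exp1_data
    model = exp1_accuracy_fit
    assert model.converged_
    rates = truth.subject_rates
    for (phase, relation) in (("choice", "AB"), ("source", "AB"), ("source", "BC")):
        sample_truth = rates[
            (rates.phase == phase) & (rates.relation == relation)
        ]["p"].mean()
        est = model.accuracy(phase, relation).mean
        assert est == pytest.approx(sample_truth, abs=0.02)


def test_mean_rhat_at_most_1_01(exp1_accuracy_fit):
    """Well-posed synthetic data: convergence diagnostics near 1."""
    rhats = exp1_accuracy_fit.summary_["rhat"].dropna()
    assert rhats.mean() <= 1.01
    assert rhats.max() <= 1.1


def test_all_failures_push_posterior_low():
    p = np.zeros(12)
    data = make_binomial_dataset(p, n_trials=40, seed=1)
    model = fit_accuracy(data, MCMCConfig(seed=11, **SMALL_MCMC))
    assert model.accuracy("choice", "AB").mean < 0.2


def test_identical_categories_give_null_contrast():
    """Two categories generated from one rate: the accuracy-difference HDI
    contains zero."""
    rng = np.random.default_rng(5)
    frames = []
    for relation in ("AB", "BC"):
        p = rng.beta(*beta_from_mode(0.75, 30.0), size=16)
        frames.append(
            make_binomial_dataset(p, n_trials=60, seed=7, relation=relation)
        )
    data = pd.concat(frames, ignore_index=True)
    model = fit_accuracy(data, MCMCConfig(seed=13, **SMALL_MCMC))
    c = model.accuracy_contrast(("choice", "AB"), ("choice", "BC"))
    assert c.hdi_low <= 0.0 <= c.hdi_high


def test_subject_posterior_matches_conjugate_form():
    """A subject's accuracy posterior is the conjugate beta-binomial.

    Two checks: (1) the exact identity — the subject-level draws match an
    independent conjugate reconstruction, p ~ Beta(a + y, b + N - y), built
    from the retained hyperparameter draws with a fresh RNG; (2) the
    asymptotic closed form — against a single Beta at the posterior-mean
    hyperparameters the draws agree up to the (real) widening induced by
    hyperparameter uncertainty, which at this problem size stays below 0.05
    total variation."""
    from scipy.special import expit

    rng = np.random.default_rng(3)
    omega, kappa = 0.7, 40.0
    p = rng.beta(*beta_from_mode(omega, kappa), size=50)
    data = make_binomial_dataset(p, n_trials=400, seed=9)
    model = AccuracyModel(seed=15, track_subject=1, **SMALL_MCMC).fit(data)
    draws = model.draws_["p_subject"][:, :, 0].ravel()
    s_idx = model.cells_.subjects.index(1)
    y = int(data[data.subject == 1]["correct"].sum())
    n = int((data.subject == 1).sum())

    # (1) exact conjugate-mixture identity, reconstructed independently
    om_draws = expit(
        model.draws_["beta0"]
        + model.draws_["beta_j"][:, :, 0]
        + model.draws_["beta_s"][:, :, s_idx]
    ).ravel()
    kp_draws = model.draws_["kappa"][:, :, 0].ravel()
    a = om_draws * (kp_draws - 2.0) + 1.0
    b = (1.0 - om_draws) * (kp_draws - 2.0) + 1.0
    ref_rng = np.random.default_rng(77)
    ref_draws = ref_rng.beta(a + y, b + n - y)
    ks = stats.ks_2samp(draws, ref_draws).statistic
    assert ks < 0.02

    # (2) asymptotic closed form at point hyperparameters
    a0, b0 = beta_from_mode(float(om_draws.mean()), float(kp_draws.mean()))
    ref = stats.beta(a0 + y, b0 + n - y)
    m, v = draws.mean(), draws.var()
    common = m * (1 - m) / v - 1
    fit_dist = stats.beta(m * common, (1 - m) * common)
    grid = np.linspace(1e-4, 1 - 1e-4, 4001)
    tv = 0.5 * np.trapezoid(np.abs(fit_dist.pdf(grid) - ref.pdf(grid)), grid)
    assert tv < 0.05


def test_experiment3_factor_terms_present_and_null():
    config = default_config(3, n_subjects=12, seed=17)
    dataset = generate(config)
    model = fit_accuracy(dataset, MCMCConfig(seed=19, **SMALL_MCMC), factor=True)
    factor_terms = [n for n in model.summaries_ if n.startswith("beta_k_")]
    assert set(factor_terms) == {"beta_k_familiar", "beta_k_novel"}
    # the generator's novelty effect defaults to zero: no credible deflection
    for name in factor_terms:
        s = model.summaries_[name]
        assert s.hdi_low <= 0.0 <= s.hdi_high
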