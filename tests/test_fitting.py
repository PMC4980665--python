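"""Likelihoods, BIC, chance model, sweeps and model recovery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from paimem.data import DATASET_COLUMNS
from paimem.fitting import (
    ChanceModel,
    NetworkGridFit,
    bic,
    chance_nll,
    dataset_nll,
    generate_from_model,
    make_model,
    predicted_profile,
    sweep,
    trial_likelihood,
)
from paimem.task import ChoiceTrial, SourceTrial, build_schedule

REMERGE_POINT = dict(w_pair=0.8, delta_bc=0.1, tau_net=0.2, thresh=0.3,
                     tau_source=0.2)


def _choice_trial(relation="AB"):
    return ChoiceTrial(
        relation=relation, cue_object="A1", target_object="B1", foil_object="B2",
        triplet_id=1, foil_triplet_id=2, session=1, order_index=0,
    )


def _rows(subject, phase, relation, correct, n, triplet0=1):
    rows = []
    for i in range(n):
        resp_ok = "target" if phase == "choice" else (
            "indirect" if relation == "AC" else "direct"
        )
        resp_bad = "foil" if phase == "choice" else (
            "direct" if relation == "AC" else "indirect"
        )
        rows.append(
            dict(
                subject=subject, experiment=1, session=1, phase=phase,
                relation=relation, triplet_id=triplet0 + i,
                response=resp_ok if correct else resp_bad, correct=bool(correct),
                rt_seconds=1.0, scene_condition="", scene_recognized=pd.NA,
            )
        )
    return rows


# -- chance model and BIC ---------------------------------------------------

def test_chance_nll_matches_published_base_row():
    schedule = build_schedule(1, seed=0)
    nll = chance_nll(schedule)
    assert nll == pytest.approx(480 * math.log(2), abs=1e-9)
    assert nll == pytest.approx(332.71, abs=0.01)
    assert bic(nll, 0, 24 * 480) == pytest.approx(2 * nll)


def test_chance_nll_small_schedules():
    class OneTrial:
        choice_trials = [None]
        source_trials = []

    assert chance_nll(OneTrial) == pytest.approx(math.log(2))

    class TenTrials:
        choice_trials = [None] * 5
        source_trials = [None] * 5

    assert chance_nll(TenTrials) == pytest.approx(10 * math.log(2), abs=1e-6)
    assert chance_nll(TenTrials) == pytest.approx(6.931, abs=1e-3)


def test_bic_formula():
    assert bic(332.0, 0, 11520) == pytest.approx(664.0)
    assert bic(0.0, 0, 1) == pytest.approx(0.0)
    assert bic(250.0, 5, 11520) == pytest.approx(546.76, abs=0.01)
    with pytest.raises(ValueError):
        bic(1.0, -1, 10)
    with pytest.raises(ValueError):
        bic(1.0, 0, 0)


# -- trial likelihood -------------------------------------------------------

def test_chance_trial_likelihood():
    model = ChanceModel()
    trial = _choice_trial()
    assert trial_likelihood(model, trial, "target") == 0.5
    assert trial_likelihood(model, trial, "foil") == 0.5


def test_trial_likelihood_complement_law():
    model = make_model("remerge", REMERGE_POINT)
    for relation in ("AB", "BC", "AC"):
        trial = _choice_trial(relation)
        p = trial_likelihood(model, trial, "target")
        assert trial_likelihood(model, trial, "foil") == pytest.approx(1 - p)
        src = SourceTrial(
            parent_choice=trial,
            correct_answer="indirect" if relation == "AC" else "direct",
            order_index=1,
        )
        q = trial_likelihood(model, src, "direct")
        assert trial_likelihood(model, src, "indirect") == pytest.approx(1 - q)


def test_source_likelihood_half_at_threshold():
    point = dict(REMERGE_POINT)
    model = make_model("remerge", point)
    x = model.mismatch("BC")
    at_thresh = make_model("remerge", {**point, "thresh": x})
    assert at_thresh.p_direct("BC") == pytest.approx(0.5, abs=1e-9)


# -- dataset NLL ------------------------------------------------------------

def test_dataset_nll_hand_summed_toy():
    """Ten trials with known model probabilities: NLL equals the hand sum."""
    model = make_model("remerge", REMERGE_POINT)
    rows = (
        _rows(1, "choice", "AB", True, 3)
        + _rows(1, "choice", "AB", False, 1, triplet0=4)
        + _rows(1, "choice", "AC", True, 2, triplet0=5)
        + _rows(1, "source", "AB", True, 2)
        + _rows(1, "source", "AB", False, 1, triplet0=3)
        + _rows(1, "source", "AB", True, 1, triplet0=4)  # parent wrong: excluded
    )
    data = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    p_ab = model.p_choice_correct("AB")
    p_ac = model.p_choice_correct("AC")
    p_src = model.p_direct("AB")
    expected = -(
        3 * math.log(p_ab) + math.log(1 - p_ab) + 2 * math.log(p_ac)
        + 2 * math.log(p_src) + math.log(1 - p_src)
    )
    assert dataset_nll(model, data) == pytest.approx(expected, rel=1e-12)


def test_dataset_nll_excludes_sources_of_wrong_choices():
    model = ChanceModel()
    rows = _rows(1, "choice", "AB", False, 2) + _rows(1, "source", "AB", True, 2)
    data = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    # only the two choice trials remain: 2 * ln 2
    assert dataset_nll(model, data) == pytest.approx(2 * math.log(2))


def test_dataset_nll_per_participant_scaling():
    model = ChanceModel()
    rows = _rows(1, "choice", "AB", True, 4) + _rows(2, "choice", "AB", True, 4)
    data = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    assert dataset_nll(model, data) == pytest.approx(4 * math.log(2))


def test_perfect_prediction_gives_zero_nll():
    class Oracle(ChanceModel):
        def p_choice_correct(self, relation):
            return 1.0

    data = pd.DataFrame(_rows(1, "choice", "AB", True, 1), columns=DATASET_COLUMNS)
    assert dataset_nll(Oracle(), data) == pytest.approx(0.0)


# -- sweep ------------------------------------------------------------------

@pytest.fixture(scope="module")
def remerge_dataset():
    schedule = build_schedule(1, seed=5)
    model = make_model("remerge", REMERGE_POINT)
    return schedule, generate_from_model(model, schedule, n_subjects=24, seed=5)


def test_single_point_sweep(remerge_dataset):
    _, data = remerge_dataset
    grid = {k: [v] for k, v in REMERGE_POINT.items()}
    result = sweep("remerge", grid, data)
    assert result.best_params == REMERGE_POINT
    assert result.n_params == 5


def test_empty_grid_rejected(remerge_dataset):
    _, data = remerge_dataset
    with pytest.raises(ValueError):
        sweep("remerge", {}, data)
    with pytest.raises(ValueError):
        sweep("remerge", {"w_pair": []}, data)


def test_sweep_is_exhaustive(remerge_dataset):
    """The winner's NLL is <= the NLL of every grid point."""
    _, data = remerge_dataset
    grid = {
        "w_pair": [0.6, 0.8, 1.0], "delta_bc": [0.0, 0.1], "tau_net": [0.2],
        "thresh": [0.2, 0.3], "tau_source": [0.1, 0.2],
    }
    result = sweep("remerge", grid, data)
    names = sorted(grid)
    for values in itertools.product(*(grid[n] for n in names)):
        params = dict(zip(names, values))
        model = make_model("remerge", params)
        assert result.nll_per_participant <= dataset_nll(model, data) + 1e-9


def test_sweep_recovers_generating_point(remerge_dataset):
    """A grid containing the generating parameters wins it back (or ties
    within 0.5% of its NLL)."""
    _, data = remerge_dataset
    grid = {
        "w_pair": [0.5, 0.8, 1.1], "delta_bc": [0.0, 0.1, 0.25],
        "tau_net": [0.15, 0.2, 0.3], "thresh": [0.15, 0.3, 0.5],
        "tau_source": [0.1, 0.2, 0.4],
    }
    result = sweep("remerge", grid, data)
    truth_nll = dataset_nll(make_model("remerge", REMERGE_POINT), data)
    assert result.nll_per_participant <= truth_nll * 1.005
    if result.best_params != REMERGE_POINT:
        assert result.nll_per_participant == pytest.approx(truth_nll, rel=5e-3)


def test_blend3_sweep_restricted_to_zero_delta_matches_blend2(remerge_dataset):
    _, data = remerge_dataset
    base = {
        "w_blend": [0.5, 0.8], "w_pair": [0.4, 0.7], "tau_net": [0.2, 0.25],
        "thresh": [0.2, 0.4], "tau_source": [0.1, 0.3],
    }
    r2 = sweep("blend_2", base, data)
    r3 = sweep("blend_3", {**base, "delta_bc": [0.0]}, data)
    assert r3.nll_per_participant == pytest.approx(r2.nll_per_participant, abs=1e-9)
    assert {k: v for k, v in r3.best_params.items() if k != "delta_bc"} == r2.best_params


def test_chance_sweep(remerge_dataset):
    _, data = remerge_dataset
    result = sweep("chance", {}, data)
    assert result.n_params == 0
    n_obs = result.n_obs_total
    assert result.nll_per_participant == pytest.approx(n_obs / 24 * math.log(2))


# -- predicted profiles -----------------------------------------------------

def test_chance_profile_flat():
    prof = predicted_profile(ChanceModel())
    assert all(v == 0.5 for v in prof.choice.values())
    assert all(v == 0.5 for v in prof.source.values())


def test_blend1_profile_choice_equal():
    prof = predicted_profile(
        make_model("blend_1", dict(w_blend=0.8, tau_net=0.2, thresh=0.3,
                                   tau_source=0.2))
    )
    vals = list(prof.choice.values())
    assert vals[0] == pytest.approx(vals[1], abs=1e-10)
    assert vals[1] == pytest.approx(vals[2], abs=1e-10)


def test_profile_drops_ac_when_untested():
    schedule = build_schedule(4, seed=1)
    # restrict to AB/BC rows the way experiment 4 omits AC for half; profile
    # keeps AC only if the schedule tests it
    prof = predicted_profile(ChanceModel(), schedule)
    assert "AC" in prof.choice  # experiment 4 still tests AC for half
    frame = prof.as_frame()
    assert set(frame.columns) == {"phase", "relation", "p_correct"}


def test_network_grid_fit_estimator(remerge_dataset):
    _, data = remerge_dataset
    grid = {k: [v] for k, v in REMERGE_POINT.items()}
    fit = NetworkGridFit(family="remerge", grid=grid).fit(data)
    assert fit.best_params_ == REMERGE_POINT
    assert fit.bic_ == pytest.approx(
        2 * fit.nll_ + 5 * math.log(fit.result_.n_obs_total)
    )
    # sklearn param plumbing
    assert NetworkGridFit(family="blend_1").get_params()["family"] == "blend_1"
    cloned = NetworkGridFit(**fit.get_params())
    assert cloned.family == "remerge"
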