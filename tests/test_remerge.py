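"""REMERGE network: structure, dynamics (vs. root-finding oracle), judgments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import root
from scipy.special import expit, softmax

from paimem.networks.remerge import (
    RemergeNetwork,
    RemergeParams,
    build_remerge,
    choice_probability,
    mismatch_activity,
    source_direct_probability,
)

from conftest import make_triplets

TOY = RemergeParams(w_pair=0.8, delta_bc=0.1, tau_net=0.2, thresh=0.3, tau_source=0.2)


def fixed_point_oracle(network, external_input, start=None):
    """Independent solver for the same update equations.

    Solves the coupled fixed-point system with scipy's hybrid root finder
    (no damped iteration involved); the residual is written directly from the
    model equations.
    """
    p = network.params
    W = network.W
    nf, nc = W.shape
    e = np.zeros(nf)
    for obj in external_input:
        e[network.feature_index[obj]] = 1.0
    theta0 = p.theta0_value

    def residual(x):
        a_f, a_c = x[:nf], x[nf:]
        r_f = expit((e + W @ a_c - theta0) / p.tau_net) - a_f
        r_c = softmax(W.T @ a_f / p.tau_net) - a_c
        return np.concatenate([r_f, r_c])

    if start is None:
        a_f0 = expit((e - theta0) / p.tau_net)
        a_c0 = softmax(W.T @ a_f0 / p.tau_net)
        start = np.concatenate([a_f0, a_c0])
    sol = root(residual, start, method="hybr", tol=1e-12)
    assert sol.success
    return sol.x[:nf], sol.x[nf:]


# -- structure --------------------------------------------------------------

def test_unit_counts():
    net = build_remerge(make_triplets(16), TOY)
    assert len(net.feature_names) == 48
    assert len(net.conjunct_names) == 32


def test_weight_matrix_enumeration():
    """Two triplets, w=3, reduction 0.5: every AB conjunct links its two
    features at 3, every BC conjunct at 2.5; nothing else is connected, and
    the implied full weight matrix is symmetric (bidirectional weights)."""
    params = RemergeParams(w_pair=3.0, delta_bc=0.5, tau_net=0.2, thresh=0.1,
                           tau_source=0.1)
    net = build_remerge(make_triplets(2), params)
    W = net.W
    assert W.shape == (6, 4)
    assert np.count_nonzero(W) == 8  # 2 features per conjunct, 4 conjuncts
    assert set(np.round(W[W != 0], 10)) == {3.0, 2.5}
    fi, ci = net.feature_index, {n: j for j, n in enumerate(net.conjunct_names)}
    assert W[fi["A1"], ci["AB1"]] == 3.0
    assert W[fi["B1"], ci["AB1"]] == 3.0
    assert W[fi["B1"], ci["BC1"]] == 2.5
    assert W[fi["C1"], ci["BC1"]] == 2.5
    assert W[fi["A1"], ci["BC1"]] == 0.0
    # bidirectional symmetric weights: the full (features+conjuncts) matrix
    n = W.shape[0] + W.shape[1]
    full = np.zeros((n, n))
    full[: W.shape[0], W.shape[0]:] = W
    full[W.shape[0]:, : W.shape[0]] = W.T
    assert np.array_equal(full, full.T)


def test_degenerate_asymmetry_equal_weights():
    params = RemergeParams(w_pair=1.0, delta_bc=0.0, tau_net=0.2, thresh=0.1,
                           tau_source=0.1)
    net = build_remerge(make_triplets(3), params)
    assert set(np.unique(net.W[net.W != 0])) == {1.0}


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(w_pair=-1.0), dict(delta_bc=-0.1), dict(delta_bc=0.9),
        dict(tau_net=0.0), dict(tau_source=0.0), dict(thresh=-0.2),
    ],
)
def test_invalid_params_rejected(kwargs):
    base = dict(w_pair=0.8, delta_bc=0.1, tau_net=0.2, thresh=0.3, tau_source=0.2)
    with pytest.raises(ValueError):
        RemergeParams(**{**base, **kwargs})


def test_empty_input_rejected():
    net = build_remerge(make_triplets(2), TOY)
    with pytest.raises(ValueError):
        net.settle(set())


def test_unknown_object_rejected():
    net = build_remerge(make_triplets(2), TOY)
    with pytest.raises(ValueError):
        net.choice_probability("A1", "B1", "B99")


# -- dynamics ---------------------------------------------------------------

def test_near_zero_weights_give_uniform_conjuncts_and_chance_choice():
    params = RemergeParams(w_pair=1e-9, delta_bc=0.0, tau_net=0.2, thresh=0.1,
                           tau_source=0.1)
    net = build_remerge(make_triplets(4), params)
    state = net.settle({"A1", "B1", "B2"})
    np.testing.assert_allclose(state.conjuncts, 1 / 8, atol=1e-6)
    assert net.choice_probability("A1", "B1", "B2") == pytest.approx(0.5, abs=1e-6)


def test_conjuncts_form_simplex_and_features_bounded():
    net = build_remerge(make_triplets(16), TOY)
    state = net.settle({"A1", "C1", "C2"})
    assert state.converged
    assert state.conjuncts.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(state.conjuncts >= 0)
    assert np.all((state.features >= 0) & (state.features <= 1))


def test_settle_matches_root_finding_oracle_on_random_networks():
    """The settled state is the fixed point of the update system, verified by
    an independent root finder on >= 20 random small networks."""
    rng = np.random.default_rng(7)
    checked = 0
    while checked < 20:
        n_trip = int(rng.integers(2, 5))
        params = RemergeParams(
            w_pair=float(rng.uniform(0.4, 1.6)),
            delta_bc=float(rng.uniform(0.0, 0.3)),
            tau_net=float(rng.uniform(0.12, 0.35)),
            thresh=0.3,
            tau_source=0.2,
        )
        if params.delta_bc >= params.w_pair:
            continue
        net = RemergeNetwork(make_triplets(n_trip), params)
        objs = [o for t in net.triplets for o in t.objects()]
        k = int(rng.integers(1, 4))
        inputs = set(rng.choice(objs, size=k, replace=False).tolist())
        state = net.settle(inputs)
        a_f, a_c = fixed_point_oracle(
            net, inputs, start=np.concatenate([state.features, state.conjuncts])
        )
        np.testing.assert_allclose(state.features, a_f, atol=1e-6)
        np.testing.assert_allclose(state.conjuncts, a_c, atol=1e-6)
        checked += 1


def test_toy_network_choice_and_mismatch_match_oracle():
    """AC inference on a 2-triplet toy network: probability and mismatch
    recomputed from the oracle's fixed points, not from the package path."""
    params = RemergeParams(w_pair=3.0, delta_bc=0.5, tau_net=0.2, thresh=0.3,
                           tau_source=0.2)
    net = RemergeNetwork(make_triplets(2), params)
    # choice: P(C1 over C2 | cue A1)
    p_pkg = net.choice_probability("A1", "C1", "C2")
    state = net.settle({"A1", "C1", "C2"})
    a_f, a_c = fixed_point_oracle(
        net, {"A1", "C1", "C2"},
        start=np.concatenate([state.features, state.conjuncts]),
    )
    r = net.W @ a_c
    fi = net.feature_index
    p_oracle = float(expit((r[fi["C1"]] - r[fi["C2"]]) / params.tau_net))
    assert p_pkg == pytest.approx(p_oracle, abs=1e-8)
    assert p_pkg > 0.5
    # mismatch for the B1-C1 source probe: strongest off-pair recall over the
    # two cue-directed runs, from oracle fixed points
    runs = []
    rest_state = net.resting_state()
    rest_f, _ = fixed_point_oracle(
        net, set(),
        start=np.concatenate([rest_state.features, rest_state.conjuncts]),
    )
    for cue in ("B1", "C1"):
        st = net.settle({cue})
        af, _ = fixed_point_oracle(
            net, {cue}, start=np.concatenate([st.features, st.conjuncts])
        )
        mask = np.zeros(len(net.feature_names), bool)
        mask[[fi["B1"], fi["C1"]]] = True
        runs.append(np.maximum(af - rest_f, 0.0)[~mask].sum())
    x_oracle = max(runs)
    assert net.source_judgment(("B1", "C1")).mismatch_x == pytest.approx(
        x_oracle, abs=1e-8
    )


def test_mismatch_zero_for_near_zero_weights():
    params = RemergeParams(w_pair=1e-9, delta_bc=0.0, tau_net=0.2, thresh=0.1,
                           tau_source=0.1)
    net = build_remerge(make_triplets(4), params)
    assert net.source_judgment(("A1", "B1")).mismatch_x == pytest.approx(0.0, abs=1e-9)


def test_mismatch_ordering_ac_exceeds_ab():
    """Judging a never-studied AC pair recalls the linking B object; judging a
    studied AB pair recalls almost nothing off-pair."""
    net = build_remerge(make_triplets(16), TOY)
    x_ab = net.source_judgment(("A1", "B1")).mismatch_x
    x_bc = net.source_judgment(("B1", "C1")).mismatch_x
    x_ac = net.source_judgment(("A1", "C1")).mismatch_x
    assert x_ac > x_bc >= x_ab


def test_symmetry_at_zero_asymmetry():
    """Without proactive interference AB and BC are equivalent: source
    mismatches are exactly equal, choice probabilities near-equal."""
    params = RemergeParams(w_pair=0.9, delta_bc=0.0, tau_net=0.2, thresh=0.3,
                           tau_source=0.2)
    net = build_remerge(make_triplets(16), params)
    assert net.source_judgment(("A1", "B1")).mismatch_x == pytest.approx(
        net.source_judgment(("B1", "C1")).mismatch_x, abs=1e-9
    )
    p_ab = net.choice_probability("A1", "B1", "B2")
    p_bc = net.choice_probability("B1", "C1", "C2")
    assert p_ab == pytest.approx(p_bc, abs=5e-3)


def test_asymmetry_direction_with_interference():
    """With weaker BC encoding: AB choice >= BC choice and AB direct-judgment
    probability >= BC's, across parameter settings."""
    rng = np.random.default_rng(3)
    for _ in range(6):
        params = RemergeParams(
            w_pair=float(rng.uniform(0.6, 1.2)),
            delta_bc=float(rng.uniform(0.03, 0.25)),
            tau_net=float(rng.uniform(0.15, 0.3)),
            thresh=0.3,
            tau_source=0.2,
        )
        net = build_remerge(make_triplets(16), params)
        assert net.choice_probability("A1", "B1", "B2") >= net.choice_probability(
            "B1", "C1", "C2"
        ) - 1e-9
        p_ab = net.source_judgment(("A1", "B1")).p_direct
        p_bc = net.source_judgment(("B1", "C1")).p_direct
        assert p_ab >= p_bc - 1e-9


# -- source probability mapping --------------------------------------------

def test_source_probability_closed_forms():
    params = TOY
    assert source_direct_probability(params.thresh, params) == pytest.approx(0.5)
    assert source_direct_probability(
        params.thresh + params.tau_source, params
    ) == pytest.approx(1.0 / (1.0 + np.e), abs=1e-12)
    sharp = RemergeParams(w_pair=0.8, delta_bc=0.1, tau_net=0.2, thresh=0.3,
                          tau_source=1e-9)
    assert source_direct_probability(0.1, sharp) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        source_direct_probability(-0.1, params)


@settings(max_examples=60, deadline=None)
@given(
    x1=st.floats(0.0, 5.0),
    dx=st.floats(1e-6, 5.0),
    thresh=st.floats(0.0, 2.0),
    tau=st.floats(0.01, 2.0),
)
def test_source_probability_strictly_decreasing(x1, dx, thresh, tau):
    params = RemergeParams(w_pair=1.0, delta_bc=0.0, tau_net=0.2, thresh=thresh,
                           tau_source=tau)
    p_hi = source_direct_probability(x1, params)
    p_lo = source_direct_probability(x1 + dx, params)
    assert p_lo <= p_hi
    # strict wherever the logistic has not saturated in floating point
    if 1e-9 < p_lo and p_hi < 1 - 1e-9:
        assert p_lo < p_hi


def test_module_level_wrappers(exp1_schedule):
    net = build_remerge(make_triplets(16), TOY)
    trial = next(c for c in exp1_schedule.choice_trials if c.relation == "AB")
    # wrapper and method agree on a trial drawn from a real schedule
    if trial.triplet_id <= 16 and trial.foil_triplet_id <= 16:
        assert choice_probability(net, trial) == net.choice_probability(
            trial.cue_object, trial.target_object, trial.foil_object
        )
    state = net.settle({"A1"})
    assert mismatch_activity(state) >= 0.0
    assert mismatch_activity(state, expected=("A1", "B1")) <= mismatch_activity(state)
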