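"""REMERGE: a recurrent, retrieval-based network for the PAI task.

The network has a feature layer (one unit per object), a conjunctive layer
(one unit per *studied pair*, an idealization of pattern-separated hippocampal
traces), and a response layer read out from conjunctive activity.  Feature and
conjunctive layers are linked by bidirectional symmetric excitatory weights;
"big-loop" recurrence — output fed back in as new input — lets the network
chain across separate traces (A1-B1, B1-C1) at retrieval, supporting AC
inference without ever storing an integrated A-B-C representation.

Proactive interference during BC study is modeled as a subtractive weight
reduction ``delta_bc`` on BC-conjunct connections.

Five free parameters: ``w_pair`` (feature<->AB-conjunct weight magnitude),
``delta_bc`` (BC weight reduction), ``tau_net`` (temperature shared by the
feature, conjunctive and response layers), and for source judgments ``thresh``
(mismatch threshold) and ``tau_source`` (source-judgment temperature).

Source ("direct"/"indirect") judgments use the amount of *mismatching
activity* on the feature layer: the network is probed with each member of the
judged pair in turn (recall-to-reject), and each run's mismatch is the summed
above-rest activation of units outside the pair.  High mismatch (e.g. recall
of B when judging A-C) is evidence that the probed pair was never experienced
as one episode; partial recall of A when judging B-C — a consequence of the
weaker BC encoding — is what drags BC source judgments toward chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from ..task import Triplet
from .common import (
    conjunctive_activation,
    default_theta0,
    feature_activation,
    floored_mismatch,
    response_softmax_pair,
)

__all__ = [
    "RemergeParams",
    "NetworkState",
    "SourceJudgment",
    "RemergeNetwork",
    "build_remerge",
    "settle",
    "choice_probability",
    "mismatch_activity",
    "source_direct_probability",
]

N_FREE_PARAMS_REMERGE = 5


@dataclass(frozen=True)
class RemergeParams:
    """Free parameters (5) plus fixed numerical settings of the dynamics."""

    w_pair: float
    delta_bc: float
    tau_net: float
    thresh: float
    tau_source: float
    # fixed numerical settings, not free parameters
    theta0: float | None = None  # default: rest activation 0.05
    damping: float = 0.2
    tol: float = 1e-9  # on the undamped residual, so the state is within
    max_iters: int = 2000  # ~tol/(1-contraction) of the true fixed point

    def __post_init__(self):
        if self.w_pair <= 0:
            raise ValueError("w_pair must be > 0")
        if not 0 <= self.delta_bc < self.w_pair:
            raise ValueError("delta_bc must satisfy 0 <= delta_bc < w_pair")
        if self.w_pair - self.delta_bc <= 0:
            raise ValueError("effective BC weight w_pair - delta_bc must be > 0")
        if self.tau_net <= 0:
            raise ValueError("tau_net must be > 0")
        if self.thresh < 0:
            raise ValueError("thresh must be >= 0")
        if self.tau_source <= 0:
            raise ValueError("tau_source must be > 0")

    @property
    def theta0_value(self) -> float:
        return default_theta0(self.tau_net) if self.theta0 is None else self.theta0


@dataclass
class NetworkState:
    """Settled (or truncated) activation state of the network."""

    features: np.ndarray  # in [0, 1]
    conjuncts: np.ndarray  # probability simplex (softmax output)
    external_input: frozenset[str]
    iterations_used: int
    converged: bool
    _network: "RemergeNetwork" = field(repr=False, default=None)

    @property
    def feature_activations(self) -> dict[str, float]:
        return dict(zip(self._network.feature_names, self.features.tolist()))

    @property
    def conjunctive_activations(self) -> dict[str, float]:
        return dict(zip(self._network.conjunct_names, self.conjuncts.tolist()))

    @property
    def response_activations(self) -> dict[str, float]:
        r = self._network.response_values(self)
        return dict(zip(self._network.feature_names, r.tolist()))


@dataclass(frozen=True)
class SourceJudgment:
    mismatch_x: float
    p_direct: float


class RemergeNetwork:
    """Weights and dynamics for one set of studied triplets."""

    def __init__(self, triplets: list[Triplet], params: RemergeParams):
        if len(triplets) < 1:
            raise ValueError("need at least one triplet")
        self.params = params
        self.triplets = list(triplets)
        self.feature_names: list[str] = []
        for t in self.triplets:
            self.feature_names.extend(t.objects())
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("object identifiers must be unique across triplets")
        self.feature_index = {name: i for i, name in enumerate(self.feature_names)}
        self.conjunct_names: list[str] = []
        rows, cols, vals = [], [], []
        w_ab = params.w_pair
        w_bc = params.w_pair - params.delta_bc
        for t in self.triplets:
            for kind, w in (("AB", w_ab), ("BC", w_bc)):
                j = len(self.conjunct_names)
                self.conjunct_names.append(f"{kind}{t.triplet_id}")
                for obj in t.pair(kind):
                    rows.append(self.feature_index[obj])
                    cols.append(j)
                    vals.append(w)
        self.W = np.zeros((len(self.feature_names), len(self.conjunct_names)))
        self.W[rows, cols] = vals
        self._rest: np.ndarray | None = None

    # -- dynamics ----------------------------------------------------------

    def _input_vector(self, external_input) -> np.ndarray:
        e = np.zeros(len(self.feature_names))
        for obj in external_input:
            if obj not in self.feature_index:
                raise ValueError(f"object {obj!r} not part of this network")
            e[self.feature_index[obj]] = 1.0
        return e

    def _settle(self, e: np.ndarray) -> NetworkState:
        """Damped synchronous updates of the constraint-satisfaction system.

        Feature update: a_f <- logistic((e + W a_c - theta0) / tau_net)
        Conjunct update: a_c <- softmax(W^T a_f / tau_net)
        both relaxed as a <- (1 - damping) a + damping * f(net).
        Deterministic: there is no randomness in the dynamics.
        """
        p = self.params
        theta0, tau = p.theta0_value, p.tau_net
        a_f = feature_activation(e, theta0, tau)
        a_c = conjunctive_activation(self.W.T @ a_f, tau)
        lam = p.damping
        converged = False
        it = 0
        for it in range(1, p.max_iters + 1):
            new_c = conjunctive_activation(self.W.T @ a_f, tau)
            new_f = feature_activation(e + self.W @ a_c, theta0, tau)
            # residual of the (undamped) update system
            delta = max(
                np.max(np.abs(new_f - a_f)), np.max(np.abs(new_c - a_c))
            )
            a_f = (1 - lam) * a_f + lam * new_f
            a_c = (1 - lam) * a_c + lam * new_c
            if delta < p.tol:
                converged = True
                break
        return NetworkState(
            features=a_f,
            conjuncts=a_c,
            external_input=frozenset(
                self.feature_names[i] for i in np.flatnonzero(e)
            ),
            iterations_used=it,
            converged=converged,
            _network=self,
        )

    def settle(self, external_input, max_iters: int | None = None,
               tol: float | None = None) -> NetworkState:
        if not external_input:
            raise ValueError("external_input must name at least one object")
        if max_iters is not None or tol is not None:
            params = RemergeParams(
                **{
                    **_params_dict(self.params),
                    "max_iters": max_iters or self.params.max_iters,
                    "tol": tol or self.params.tol,
                }
            )
            net = RemergeNetwork(self.triplets, params)
            return net._settle(net._input_vector(external_input))
        return self._settle(self._input_vector(external_input))

    def resting_state(self) -> NetworkState:
        """No-input fixed point; the per-unit baseline for mismatch."""
        if self._rest is None:
            self._rest = self._settle(np.zeros(len(self.feature_names)))
        return self._rest

    # -- readout -----------------------------------------------------------

    def response_values(self, state: NetworkState) -> np.ndarray:
        """One feedforward pass conjunctive -> response with the same weights."""
        return self.W @ state.conjuncts

    def choice_probability(self, cue: str, target: str, foil: str) -> float:
        for obj in (cue, target, foil):
            if obj not in self.feature_index:
                raise ValueError(f"object {obj!r} not part of this network")
        state = self._settle(self._input_vector({cue, target, foil}))
        r = self.response_values(state)
        return response_softmax_pair(
            r[self.feature_index[target]], r[self.feature_index[foil]], self.params.tau_net
        )

    def mismatch_activity(self, state: NetworkState, expected=None) -> float:
        """Summed above-rest activity of feature units outside ``expected``.

        ``expected`` defaults to the state's external input; for source
        judgments it is the judged pair (recall of either member is consistent
        with the probe and does not count as mismatch).
        """
        expected = state.external_input if expected is None else expected
        mask = np.zeros(len(self.feature_names), dtype=bool)
        for obj in expected:
            mask[self.feature_index[obj]] = True
        return floored_mismatch(state.features, self.resting_state().features, mask)

    def source_judgment(self, probe_pair) -> SourceJudgment:
        """Recall-to-reject source judgment for the judged pair.

        The network is probed with each member of the pair in turn; each run's
        mismatch is the above-rest recall of units outside the pair, and the
        judgment is driven by the stronger of the two signals.  Probing from
        single objects (rather than clamping the pair) is what lets partially
        active competing traces — e.g. partial A recall during a BC probe when
        BC encoding is weaker — surface as mismatching recall.
        """
        pair = tuple(probe_pair)
        x = max(
            self.mismatch_activity(self.settle({cue}), expected=pair)
            for cue in pair
        )
        return SourceJudgment(x, source_direct_probability(x, self.params))


def _params_dict(p: RemergeParams) -> dict:
    return dict(
        w_pair=p.w_pair, delta_bc=p.delta_bc, tau_net=p.tau_net, thresh=p.thresh,
        tau_source=p.tau_source, theta0=p.theta0, damping=p.damping,
        tol=p.tol, max_iters=p.max_iters,
    )


# -- module-level operation wrappers ---------------------------------------

def build_remerge(triplets: list[Triplet], params: RemergeParams) -> RemergeNetwork:
    return RemergeNetwork(triplets, params)


def settle(network: RemergeNetwork, external_input, max_iters: int | None = None,
           tol: float | None = None) -> NetworkState:
    return network.settle(external_input, max_iters=max_iters, tol=tol)


def choice_probability(network: RemergeNetwork, trial) -> float:
    """P(choose target over foil); external input is {cue, target, foil}."""
    return network.choice_probability(
        trial.cue_object, trial.target_object, trial.foil_object
    )


def mismatch_activity(state: NetworkState, expected=None) -> float:
    """Mismatch of a settled state relative to the expected object set."""
    return state._network.mismatch_activity(state, expected=expected)


def source_direct_probability(mismatch_x: float, params) -> float:
    """P("direct") = logistic((thresh - x) / tau_source).

    Strictly decreasing in the mismatch signal, and exactly 0.5 when the
    mismatch equals the threshold.
    """
    if params.tau_source <= 0:
        raise ValueError("tau_source must be > 0")
    if mismatch_x < 0:
        raise ValueError("mismatch_x must be >= 0")
    return float(expit((params.thresh - mismatch_x) / params.tau_source))
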