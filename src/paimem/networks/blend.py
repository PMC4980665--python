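"""Blend models: feedforward, encoding-based competitors to REMERGE.

Encoding-based accounts hold that overlapping pairs A-B and B-C are integrated
*at study* into a blended A-B-C representation that supports inference
directly at test.  Three nested variants are implemented, sharing REMERGE's
activation functions but with **no recurrence** — a single forward pass
(feature -> conjunctive), plus at most one backward pass (conjunctive ->
feature) used solely to compute the mismatching-activity signal for source
judgments:

- ``blend_1`` (4 free parameters): one ABC conjunct per triplet, connected to
  all three feature units at ``w_blend``.
- ``blend_2`` (5): additionally pattern-separated AB and BC conjuncts at a
  shared ``w_pair``.
- ``blend_3`` (6): as blend_2, with proactive interference — BC-conjunct
  weights reduced to ``w_pair - delta_bc``.

Because the ABC unit is symmetric in its three features, blend_1 produces
identical responses to direct (AB, BC) and indirect (AC) probes; it cannot
separate them, and its source accuracy on balanced probes is exactly chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..task import Triplet
from .common import (
    conjunctive_activation,
    default_theta0,
    feature_activation,
    floored_mismatch,
    response_softmax_pair,
)
from .remerge import SourceJudgment, source_direct_probability

__all__ = [
    "BlendParams",
    "BlendState",
    "BlendNetwork",
    "build_blend",
    "blend_forward",
    "blend_choice_probability",
    "blend_mismatch",
    "BLEND_N_FREE_PARAMS",
]

BLEND_VARIANTS = ("blend_1", "blend_2", "blend_3")
BLEND_N_FREE_PARAMS = {"blend_1": 4, "blend_2": 5, "blend_3": 6}


@dataclass(frozen=True)
class BlendParams:
    """Parameters of one blend variant.

    Supplying a parameter the variant does not use is rejected, preserving the
    4 / 5 / 6 free-parameter counts of blend_1 / blend_2 / blend_3.
    """

    variant: str
    w_blend: float
    tau_net: float
    thresh: float
    tau_source: float
    w_pair: float | None = None  # blend_2, blend_3
    delta_bc: float | None = None  # blend_3 only
    theta0: float | None = None
    damping: float = 0.0  # unused; kept for config-file compatibility
    tol: float = 0.0
    max_iters: int = 1

    def __post_init__(self):
        if self.variant not in BLEND_VARIANTS:
            raise ValueError(f"unknown blend variant {self.variant!r}")
        if self.w_blend <= 0:
            raise ValueError("w_blend must be > 0")
        if self.tau_net <= 0:
            raise ValueError("tau_net must be > 0")
        if self.thresh < 0:
            raise ValueError("thresh must be >= 0")
        if self.tau_source <= 0:
            raise ValueError("tau_source must be > 0")
        if self.variant == "blend_1":
            if self.w_pair is not None or self.delta_bc is not None:
                raise ValueError("blend_1 takes neither w_pair nor delta_bc")
        elif self.variant == "blend_2":
            if self.w_pair is None:
                raise ValueError("blend_2 requires w_pair")
            if self.delta_bc is not None:
                raise ValueError("blend_2 does not take delta_bc")
        else:  # blend_3
            if self.w_pair is None or self.delta_bc is None:
                raise ValueError("blend_3 requires w_pair and delta_bc")
            if not 0 <= self.delta_bc < self.w_pair:
                raise ValueError("delta_bc must satisfy 0 <= delta_bc < w_pair")
        if self.w_pair is not None and self.w_pair < 0:
            raise ValueError("w_pair must be >= 0")

    @property
    def n_free_params(self) -> int:
        return BLEND_N_FREE_PARAMS[self.variant]

    @property
    def theta0_value(self) -> float:
        return default_theta0(self.tau_net) if self.theta0 is None else self.theta0


@dataclass
class BlendState:
    """Result of one forward pass and (for mismatch) one backward pass."""

    features: np.ndarray
    conjuncts: np.ndarray
    reconstructed_features: np.ndarray
    external_input: frozenset[str]
    _network: "BlendNetwork" = field(repr=False, default=None)

    @property
    def feature_activations(self) -> dict[str, float]:
        return dict(zip(self._network.feature_names, self.features.tolist()))

    @property
    def conjunctive_activations(self) -> dict[str, float]:
        return dict(zip(self._network.conjunct_names, self.conjuncts.tolist()))


class BlendNetwork:
    """Feedforward network over one set of studied triplets."""

    def __init__(self, triplets: list[Triplet], params: BlendParams):
        if len(triplets) < 1:
            raise ValueError("need at least one triplet")
        self.params = params
        self.triplets = list(triplets)
        self.feature_names = [o for t in self.triplets for o in t.objects()]
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("object identifiers must be unique across triplets")
        self.feature_index = {name: i for i, name in enumerate(self.feature_names)}
        self.conjunct_names: list[str] = []
        rows, cols, vals = [], [], []

        def connect(j, objs, w):
            for obj in objs:
                rows.append(self.feature_index[obj])
                cols.append(j)
                vals.append(w)

        for t in self.triplets:
            j = len(self.conjunct_names)
            self.conjunct_names.append(f"ABC{t.triplet_id}")
            connect(j, t.objects(), params.w_blend)
            if params.variant in ("blend_2", "blend_3"):
                w_ab = params.w_pair
                w_bc = (
                    params.w_pair - params.delta_bc
                    if params.variant == "blend_3"
                    else params.w_pair
                )
                for kind, w in (("AB", w_ab), ("BC", w_bc)):
                    j = len(self.conjunct_names)
                    self.conjunct_names.append(f"{kind}{t.triplet_id}")
                    connect(j, t.pair(kind), w)
        self.W = np.zeros((len(self.feature_names), len(self.conjunct_names)))
        self.W[rows, cols] = vals
        # a conjunct with zero encoding strength is no trace at all: drop it,
        # so nested variants (e.g. blend_2 at w_pair=0) reduce exactly
        keep = np.any(self.W != 0.0, axis=0)
        self.W = self.W[:, keep]
        self.conjunct_names = [n for n, k in zip(self.conjunct_names, keep) if k]
        self._rest: BlendState | None = None

    def _input_vector(self, external_input) -> np.ndarray:
        e = np.zeros(len(self.feature_names))
        for obj in external_input:
            if obj not in self.feature_index:
                raise ValueError(f"object {obj!r} not part of this network")
            e[self.feature_index[obj]] = 1.0
        return e

    def _forward(self, e: np.ndarray) -> BlendState:
        """Single closed-form pass; no iteration anywhere."""
        p = self.params
        a_f = feature_activation(e, p.theta0_value, p.tau_net)
        a_c = conjunctive_activation(self.W.T @ a_f, p.tau_net)
        recon = feature_activation(self.W @ a_c, p.theta0_value, p.tau_net)
        return BlendState(
            features=a_f,
            conjuncts=a_c,
            reconstructed_features=recon,
            external_input=frozenset(
                self.feature_names[i] for i in np.flatnonzero(e)
            ),
            _network=self,
        )

    def forward(self, external_input) -> BlendState:
        if not external_input:
            raise ValueError("external_input must name at least one object")
        return self._forward(self._input_vector(external_input))

    def resting_state(self) -> BlendState:
        if self._rest is None:
            self._rest = self._forward(np.zeros(len(self.feature_names)))
        return self._rest

    def response_values(self, state: BlendState) -> np.ndarray:
        return self.W @ state.conjuncts

    def choice_probability(self, cue: str, target: str, foil: str) -> float:
        for obj in (cue, target, foil):
            if obj not in self.feature_index:
                raise ValueError(f"object {obj!r} not part of this network")
        state = self.forward({cue, target, foil})
        r = self.response_values(state)
        return response_softmax_pair(
            r[self.feature_index[target]], r[self.feature_index[foil]], self.params.tau_net
        )

    def mismatch_activity(self, state: BlendState, expected=None) -> float:
        """Mismatch from the backward-pass reconstruction, rest-subtracted."""
        expected = state.external_input if expected is None else expected
        mask = np.zeros(len(self.feature_names), dtype=bool)
        for obj in expected:
            mask[self.feature_index[obj]] = True
        return floored_mismatch(
            state.reconstructed_features,
            self.resting_state().reconstructed_features,
            mask,
        )

    def source_judgment(self, probe_pair) -> SourceJudgment:
        """Recall-to-reject with the same probe scheme as REMERGE: one forward
        and one backward pass per pair member, stronger mismatch wins."""
        pair = tuple(probe_pair)
        x = max(
            self.mismatch_activity(self.forward({cue}), expected=pair)
            for cue in pair
        )
        return SourceJudgment(x, source_direct_probability(x, self.params))


# -- module-level operation wrappers ---------------------------------------

def build_blend(triplets: list[Triplet], params: BlendParams) -> BlendNetwork:
    return BlendNetwork(triplets, params)


def blend_forward(network: BlendNetwork, external_input) -> BlendState:
    return network.forward(external_input)


def blend_choice_probability(network: BlendNetwork, trial) -> float:
    return network.choice_probability(
        trial.cue_object, trial.target_object, trial.foil_object
    )


def blend_mismatch(state: BlendState, expected=None) -> float:
    return state._network.mismatch_activity(state, expected=expected)
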