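"""Trial-level likelihoods, NLL/BIC model comparison, and grid sweeps.

Each network model yields, per trial category, a probability of the correct
response: for choice trials a two-option softmax over response units, for
source trials the thresholded mismatch signal.  Models are compared on the
per-participant negative log likelihood (NLL) of the behavioral data and the
Bayesian Information Criterion, ``BIC = 2 * NLL + k * ln(N)`` with ``N`` the
total observation count pooled over subjects.

Source trials whose parent choice was incorrect are excluded from the
likelihood (the source question presumes the chosen object); trials without a
response (timeouts) are dropped.

Because every triplet is architecturally equivalent, category probabilities
are computed once per parameter point from representative trials, which makes
exhaustive hyperparameter sweeps cheap.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import apply_source_exclusion, drop_timeouts
from .networks.blend import BLEND_N_FREE_PARAMS, BlendNetwork, BlendParams
from .networks.remerge import (
    N_FREE_PARAMS_REMERGE,
    RemergeNetwork,
    RemergeParams,
)
from .task import RELATIONS, ExperimentSchedule, Triplet

__all__ = [
    "FitResult",
    "PredictedProfile",
    "NetworkBehaviorModel",
    "ChanceModel",
    "make_model",
    "trial_likelihood",
    "dataset_nll",
    "bic",
    "chance_nll",
    "sweep",
    "predicted_profile",
    "NetworkGridFit",
    "MODEL_FAMILIES",
]

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-12  # inside logs only; raw probabilities are reported unfloored

MODEL_FAMILIES = ("remerge", "blend_1", "blend_2", "blend_3", "chance")

_N_FREE = {"remerge": N_FREE_PARAMS_REMERGE, "chance": 0, **BLEND_N_FREE_PARAMS}

#: default hyperparameter grids: round-number coverage of the regime where the
#: constraint-satisfaction dynamics operate (weights a small multiple of the
#: temperature; asymmetries up to ~25% of the pair weight; thresholds and
#: source temperatures spanning the observed mismatch scale)
_SOURCE_GRID = {"thresh": [0.1, 0.2, 0.3, 0.45, 0.6], "tau_source": [0.05, 0.1, 0.2, 0.35]}
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "remerge": {
        "w_pair": [0.6, 0.8, 1.0, 1.2],
        "delta_bc": [0.0, 0.05, 0.1, 0.15, 0.2],
        "tau_net": [0.15, 0.2, 0.25, 0.3],
        **_SOURCE_GRID,
    },
    "blend_1": {
        "w_blend": [0.4, 0.6, 0.8, 1.0, 1.2],
        "tau_net": [0.15, 0.2, 0.25, 0.3],
        **_SOURCE_GRID,
    },
    "blend_2": {
        "w_blend": [0.4, 0.6, 0.8, 1.0],
        "w_pair": [0.2, 0.4, 0.6, 0.9, 1.2],
        "tau_net": [0.15, 0.2, 0.25, 0.3],
        **_SOURCE_GRID,
    },
    "blend_3": {
        "w_blend": [0.4, 0.6, 0.8, 1.0],
        "w_pair": [0.4, 0.6, 0.9, 1.2],
        "delta_bc": [0.0, 0.1, 0.2, 0.3],
        "tau_net": [0.2, 0.25, 0.3],
        **_SOURCE_GRID,
    },
    "chance": {},
}

# settling results depend only on the dynamics parameters, not on the
# source-judgment threshold/temperature: share them across grid points
_DYN_KEYS = {
    "remerge": ("w_pair", "delta_bc", "tau_net"),
    "blend_1": ("w_blend", "tau_net"),
    "blend_2": ("w_blend", "w_pair", "tau_net"),
    "blend_3": ("w_blend", "w_pair", "delta_bc", "tau_net"),
}
_SHARED_CACHE: dict = {}
_SHARED_CACHE_MAX = 4096


@dataclass
class FitResult:
    model_name: str
    best_params: dict
    nll_per_participant: float
    n_params: int
    n_obs_total: int
    bic_per_participant: float

    def as_dict(self) -> dict:
        return {
            "model": self.model_name,
            "params": dict(self.best_params),
            "nll_per_participant": self.nll_per_participant,
            "n_params": self.n_params,
            "n_obs_total": self.n_obs_total,
            "bic_per_participant": self.bic_per_participant,
        }


@dataclass
class PredictedProfile:
    """Per-category predicted proportion correct (choice and source)."""

    choice: dict[str, float]  # relation -> P(correct)
    source: dict[str, float]

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"phase": ph, "relation": rel, "p_correct": d[rel]}
            for ph, d in (("choice", self.choice), ("source", self.source))
            for rel in RELATIONS
        ]
        return pd.DataFrame(rows)


def _context_triplets(n: int) -> list[Triplet]:
    return [Triplet(t, f"A{t}", f"B{t}", f"C{t}") for t in range(1, n + 1)]


class NetworkBehaviorModel:
    """A network plus its behavioral readout, with per-category caching.

    All triplets are equivalent by construction, so the probability of a
    correct response depends only on the trial category; representative trials
    (triplet 1 cued, triplet 2 donating the foil) stand in for all of them.
    ``context_size`` is the number of triplets competing in the network —
    16 for the study-test-cycle experiments (one cycle is in play at test).
    """

    def __init__(self, name: str, network, n_free_params: int,
                 shared: dict | None = None, params=None):
        self.name = name
        self.network = network
        self.n_free_params = n_free_params
        # settling results shared across grid points with the same dynamics
        self._shared = shared if shared is not None else {}
        self._params = params if params is not None else network.params

    @property
    def params(self):
        return self._params

    def p_choice_correct(self, relation: str) -> float:
        key = ("choice", relation)
        if key not in self._shared:
            t1, t2 = self.network.triplets[0], self.network.triplets[1]
            cue, target = _relation_pair(t1, relation)
            foil = _relation_pair(t2, relation)[1]
            self._shared[key] = self.network.choice_probability(cue, target, foil)
        return self._shared[key]

    def mismatch(self, relation: str) -> float:
        key = ("mismatch", relation)
        if key not in self._shared:
            t1 = self.network.triplets[0]
            probe = _relation_pair(t1, relation)
            self._shared[key] = self.network.source_judgment(probe).mismatch_x
        return self._shared[key]

    def p_direct(self, relation: str) -> float:
        """P("direct" response) when judging the correctly chosen pair."""
        from .networks.remerge import source_direct_probability

        return source_direct_probability(self.mismatch(relation), self.params)

    def p_source_correct(self, relation: str) -> float:
        p = self.p_direct(relation)
        return 1.0 - p if relation == "AC" else p


class ChanceModel:
    """Base (random) model: probability 0.5 for every response, 0 parameters."""

    name = "chance"
    n_free_params = 0
    params = None

    def p_choice_correct(self, relation: str) -> float:
        return 0.5

    def p_direct(self, relation: str) -> float:
        return 0.5

    def p_source_correct(self, relation: str) -> float:
        return 0.5


def _relation_pair(triplet: Triplet, relation: str) -> tuple[str, str]:
    if relation == "AB":
        return triplet.object_a, triplet.object_b
    if relation == "BC":
        return triplet.object_b, triplet.object_c
    if relation == "AC":
        return triplet.object_a, triplet.object_c
    raise ValueError(f"unknown relation {relation!r}")


def make_model(family: str, params: dict | None = None, context_size: int = 16):
    """Instantiate a behavior model of one family at a parameter point."""
    if family == "chance":
        return ChanceModel()
    if family not in _DYN_KEYS:
        raise ValueError(f"unknown model family {family!r}")
    if family == "remerge":
        point_params = RemergeParams(**params)
    else:
        point_params = BlendParams(variant=family, **params)
    key = (
        family,
        context_size,
        tuple((k, params.get(k)) for k in _DYN_KEYS[family]),
    )
    entry = _SHARED_CACHE.get(key)
    if entry is None:
        triplets = _context_triplets(context_size)
        if family == "remerge":
            net = RemergeNetwork(triplets, point_params)
        else:
            net = BlendNetwork(triplets, point_params)
        if len(_SHARED_CACHE) >= _SHARED_CACHE_MAX:
            _SHARED_CACHE.clear()
        entry = _SHARED_CACHE[key] = (net, {})
    net, shared = entry
    # thresh/tau_source vary across grid points sharing one settled network
    return NetworkBehaviorModel(
        family, net, _N_FREE[family], shared=shared, params=point_params
    )


# ---------------------------------------------------------------------------
# likelihoods

def trial_likelihood(model, trial, observed_response: str) -> float:
    """Probability the model assigns to the observed response on one trial."""
    phase = getattr(trial, "correct_answer", None)
    if phase is None:  # choice trial
        p = model.p_choice_correct(trial.relation)
        if observed_response == "target":
            return p
        if observed_response == "foil":
            return 1.0 - p
        raise ValueError(f"choice response must be target/foil, got {observed_response!r}")
    p_direct = model.p_direct(trial.parent_choice.relation)
    if observed_response == "direct":
        return p_direct
    if observed_response == "indirect":
        return 1.0 - p_direct
    raise ValueError(f"source response must be direct/indirect, got {observed_response!r}")


def _category_counts(dataset: pd.DataFrame) -> pd.DataFrame:
    """Observation counts per (phase, relation, correct) after exclusions."""
    data = drop_timeouts(dataset)
    data = apply_source_exclusion(data)
    counts = (
        data.groupby(["phase", "relation", "correct"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    return counts


def dataset_nll(model, dataset: pd.DataFrame) -> float:
    """Per-participant NLL over choice trials and retained source trials."""
    n_subjects = dataset["subject"].nunique()
    if n_subjects == 0:
        raise ValueError("dataset has no subjects")
    counts = _category_counts(dataset)
    total = 0.0
    for phase, relation, correct, n in counts.itertuples(index=False):
        p_correct = (
            model.p_choice_correct(relation)
            if phase == "choice"
            else model.p_source_correct(relation)
        )
        p = p_correct if correct else 1.0 - p_correct
        if p <= 0.0:
            logger.warning(
                "zero probability for %s %s correct=%s; flooring at %.0e",
                phase, relation, correct, PROB_FLOOR,
            )
        total += -n * math.log(max(p, PROB_FLOOR))
    return total / n_subjects


def bic(nll_per_participant: float, k: int, n_obs_total: int) -> float:
    """BIC = 2 * NLL + k * ln(N), N pooled over subjects."""
    if n_obs_total < 1:
        raise ValueError("n_obs_total must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2.0 * nll_per_participant + k * math.log(n_obs_total)


def chance_nll(schedule: ExperimentSchedule) -> float:
    """Per-participant NLL of the p=0.5 model: (binary observations) * ln 2."""
    n_obs = len(schedule.choice_trials) + len(schedule.source_trials)
    return n_obs * math.log(2.0)


def _n_obs_total(dataset: pd.DataFrame) -> int:
    data = apply_source_exclusion(drop_timeouts(dataset))
    return len(data)


# ---------------------------------------------------------------------------
# sweep

def sweep(
    model_family: str,
    grid_spec: dict[str, list],
    dataset: pd.DataFrame,
    context_size: int = 16,
) -> FitResult:
    """Exhaustive grid evaluation; returns the point minimizing total NLL.

    Ties are broken by lexicographic parameter order (the grid is iterated in
    sorted-key order and only strict improvements replace the incumbent).
    """
    if model_family == "chance":
        if grid_spec:
            raise ValueError("chance model has no parameters to sweep")
        model = ChanceModel()
        nll = dataset_nll(model, dataset)
        n_obs = _n_obs_total(dataset)
        return FitResult("chance", {}, nll, 0, n_obs, bic(nll, 0, n_obs))
    if not grid_spec or any(len(v) == 0 for v in grid_spec.values()):
        raise ValueError("grid_spec must give at least one value per parameter")
    names = sorted(grid_spec)
    n_obs = _n_obs_total(dataset)
    counts = _category_counts(dataset)
    best = None
    for values in itertools.product(*(sorted(grid_spec[n]) for n in names)):
        params = dict(zip(names, values))
        model = make_model(model_family, params, context_size=context_size)
        nll = _nll_from_counts(model, counts) / dataset["subject"].nunique()
        if best is None or nll < best[0] - 1e-12:
            best = (nll, params)
    nll, params = best
    k = _N_FREE[model_family]
    logger.info("sweep %s: best NLL/participant %.3f at %s", model_family, nll, params)
    return FitResult(model_family, params, nll, k, n_obs, bic(nll, k, n_obs))


def _nll_from_counts(model, counts: pd.DataFrame) -> float:
    total = 0.0
    for phase, relation, correct, n in counts.itertuples(index=False):
        p_correct = (
            model.p_choice_correct(relation)
            if phase == "choice"
            else model.p_source_correct(relation)
        )
        p = p_correct if correct else 1.0 - p_correct
        total += -n * math.log(max(p, PROB_FLOOR))
    return total


def predicted_profile(model, schedule: ExperimentSchedule | None = None) -> PredictedProfile:
    """Mean predicted proportion correct per trial category.

    With a schedule, categories are weighted by their trial counts (identical
    probabilities within a category make this the per-category probability).
    """
    choice = {rel: model.p_choice_correct(rel) for rel in RELATIONS}
    source = {rel: model.p_source_correct(rel) for rel in RELATIONS}
    if schedule is not None and not any(
        c.relation == "AC" for c in schedule.choice_trials
    ):
        choice.pop("AC")
        source.pop("AC")
    return PredictedProfile(choice=choice, source=source)


def generate_from_model(model, schedule: ExperimentSchedule, n_subjects: int,
                        seed: int) -> pd.DataFrame:
    """Simulate trial-level behavior directly from a network model.

    Every simulated subject is an independent run of the same model: per
    trial, the choice is Bernoulli with the model's category probability and
    the source response Bernoulli with its direct-probability.  Used for
    model-recovery checks (fit candidate models to data whose ground truth is
    a network).
    """
    from .data import DATASET_COLUMNS

    rng = np.random.default_rng(seed)
    trials = sorted(schedule.choice_trials, key=lambda c: (c.session, c.order_index))
    rows = []
    for s in range(1, n_subjects + 1):
        for c in trials:
            p_choice = model.p_choice_correct(c.relation)
            ok_choice = bool(rng.random() < p_choice)
            p_src = model.p_source_correct(c.relation)
            ok_src = bool(rng.random() < p_src)
            correct_answer = "indirect" if c.relation == "AC" else "direct"
            wrong_answer = "direct" if c.relation == "AC" else "indirect"
            rows.append(
                dict(
                    subject=s, experiment=schedule.experiment_id, session=c.session,
                    phase="choice", relation=c.relation, triplet_id=c.triplet_id,
                    response="target" if ok_choice else "foil", correct=ok_choice,
                    rt_seconds=1.0, scene_condition="", scene_recognized=pd.NA,
                )
            )
            rows.append(
                dict(
                    subject=s, experiment=schedule.experiment_id, session=c.session,
                    phase="source", relation=c.relation, triplet_id=c.triplet_id,
                    response=correct_answer if ok_src else wrong_answer,
                    correct=ok_src, rt_seconds=1.0, scene_condition="",
                    scene_recognized=pd.NA,
                )
            )
    return pd.DataFrame(rows, columns=DATASET_COLUMNS)


# ---------------------------------------------------------------------------
# sklearn-style estimator

class NetworkGridFit(BaseEstimator):
    """Grid-sweep fit of one network family to a behavioral dataset.

    Parameters
    ----------
    family : one of ``remerge, blend_1, blend_2, blend_3, chance``.
    grid : mapping parameter name -> list of candidate values (ignored for the
        chance model).
    context_size : number of triplets competing in the network at test.

    Attributes (after ``fit``)
    --------------------------
    result_ : FitResult with the winning point, NLL and BIC per participant.
    best_params_, nll_, bic_, n_params_ : convenience views of ``result_``.
    model_ : the behavior model at the winning point.
    """

    def __init__(self, family: str = "remerge", grid: dict | None = None,
                 context_size: int = 16):
        self.family = family
        self.grid = grid
        self.context_size = context_size

    def fit(self, X: pd.DataFrame, y=None):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        grid = self.grid if self.grid is not None else DEFAULT_GRIDS[self.family]
        self.result_ = sweep(self.family, grid, X, context_size=self.context_size)
        self.best_params_ = self.result_.best_params
        self.nll_ = self.result_.nll_per_participant
        self.bic_ = self.result_.bic_per_participant
        self.n_params_ = self.result_.n_params
        self.model_ = make_model(
            self.family, self.best_params_ or None, context_size=self.context_size
        ) if self.family != "chance" else ChanceModel()
        return self

    def predicted_profile(self, schedule: ExperimentSchedule | None = None):
        return predicted_profile(self.model_, schedule)
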