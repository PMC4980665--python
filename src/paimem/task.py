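"""Paired-associate inference (PAI) task: trial types and experiment schedules.

The PAI paradigm studies overlapping object pairs A-B and B-C drawn from
triplets A-B-C.  Memory is probed with two-alternative *choice* trials (cue on
top, target vs. familiar foil below) for the studied AB/BC relations and the
never-studied AC relation, each immediately followed by a *source* trial asking
whether the chosen object had actually been presented together with the cue
("direct") or was only related through an unseen third item ("indirect").

Four experiment variants are supported:

1. 80 triplets in 5 study-test cycles of 16; each pair studied once per cycle.
2. all study before test; each pair studied twice, with a minimum 10-trial gap
   between an AB presentation and its related BC presentation; 5-second
   response cap at test.
3. as experiment 1, plus a novel/familiar scene preceding every BC study trial
   (half novel, half familiar per session).
4. as experiment 1, but AC test trials omitted for exactly half the triplets,
   with AB/BC test order balanced across triplets.

Object identifiers are abstract labels ("A17"); no image assets are handled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Triplet",
    "EncodingTrial",
    "ChoiceTrial",
    "SourceTrial",
    "ExperimentSchedule",
    "build_schedule",
    "validate_schedule",
    "schedule_to_frame",
    "write_schedule_csv",
    "RELATIONS",
    "PAIR_KINDS",
    "N_TRIPLETS",
    "N_SESSIONS",
    "TRIPLETS_PER_SESSION",
    "RESPONSE_CAP_SECONDS",
]

PAIR_KINDS = ("AB", "BC")
RELATIONS = ("AB", "BC", "AC")

N_TRIPLETS = 80
N_SESSIONS = 5
TRIPLETS_PER_SESSION = 16

#: maximum time allowed for a test response, per experiment (seconds)
RESPONSE_CAP_SECONDS = {1: 10.0, 2: 5.0, 3: 10.0, 4: 10.0}

#: minimum number of intervening study trials between an AB presentation and a
#: related BC presentation in experiment 2
MIN_AB_BC_GAP = 10


@dataclass(frozen=True)
class Triplet:
    """Three objects linked only through the shared middle item B."""

    triplet_id: int
    object_a: str
    object_b: str
    object_c: str

    def objects(self) -> tuple[str, str, str]:
        return (self.object_a, self.object_b, self.object_c)

    def pair(self, kind: str) -> tuple[str, str]:
        if kind == "AB":
            return (self.object_a, self.object_b)
        if kind == "BC":
            return (self.object_b, self.object_c)
        raise ValueError(f"unknown pair kind {kind!r}")


@dataclass(frozen=True)
class EncodingTrial:
    triplet_id: int
    pair_kind: str
    session: int
    left_right: int  # 0: canonical order on screen, 1: flipped
    order_index: int
    preceding_scene: str | None = None  # "novel"/"familiar"; experiment 3, BC only
    scene_id: str | None = None


@dataclass(frozen=True)
class ChoiceTrial:
    relation: str
    cue_object: str
    target_object: str
    foil_object: str
    triplet_id: int
    foil_triplet_id: int
    session: int
    order_index: int


@dataclass(frozen=True)
class SourceTrial:
    parent_choice: ChoiceTrial
    correct_answer: str  # "direct" for AB/BC, "indirect" for AC
    order_index: int


@dataclass
class ExperimentSchedule:
    """Complete trial program for one experiment variant."""

    experiment_id: int
    triplets: list[Triplet]
    encoding_trials: list[EncodingTrial]
    choice_trials: list[ChoiceTrial]
    source_trials: list[SourceTrial]
    pair_repetitions: int
    cycle_structure: str  # "study-test-cycles" | "all-study-then-test"
    session_of_triplet: dict[int, int] = field(default_factory=dict)
    familiar_scenes: list[str] = field(default_factory=list)
    novel_scenes: list[str] = field(default_factory=list)
    foil_scenes: list[str] = field(default_factory=list)

    @property
    def response_cap_seconds(self) -> float:
        return RESPONSE_CAP_SECONDS[self.experiment_id]

    def triplet_by_id(self, triplet_id: int) -> Triplet:
        return self._index()[triplet_id]

    def _index(self) -> dict[int, Triplet]:
        if not hasattr(self, "_triplet_index"):
            self._triplet_index = {t.triplet_id: t for t in self.triplets}
        return self._triplet_index


def _make_triplets() -> list[Triplet]:
    return [Triplet(t, f"A{t}", f"B{t}", f"C{t}") for t in range(1, N_TRIPLETS + 1)]


def _cue_target(triplet: Triplet, relation: str) -> tuple[str, str]:
    """Cue is the earlier item of the relation; the target completes it."""
    if relation == "AB":
        return triplet.object_a, triplet.object_b
    if relation == "BC":
        return triplet.object_b, triplet.object_c
    if relation == "AC":
        return triplet.object_a, triplet.object_c
    raise ValueError(f"unknown relation {relation!r}")


def _foil_object(foil_triplet: Triplet, relation: str) -> str:
    # foil plays the same role as the target but comes from another triplet
    return _cue_target(foil_triplet, relation)[1]


def _build_test_block(
    triplets: list[Triplet],
    session: int,
    rng: np.random.Generator,
    relations_of: dict[int, tuple[str, ...]],
    order_keys: dict[tuple[int, str], float],
    index_by_id: dict[int, Triplet],
) -> tuple[list[ChoiceTrial], list[SourceTrial]]:
    """Assemble choice trials in key order, each followed by its source trial."""
    trials = []
    for t in triplets:
        for rel in relations_of[t.triplet_id]:
            trials.append((order_keys[(t.triplet_id, rel)], t.triplet_id, rel))
    trials.sort()
    ids = [t.triplet_id for t in triplets]
    choice_trials, source_trials = [], []
    for pos, (_, tid, rel) in enumerate(trials):
        trip = index_by_id[tid]
        cue, target = _cue_target(trip, rel)
        foil_tid = int(rng.choice([i for i in ids if i != tid]))
        foil = _foil_object(index_by_id[foil_tid], rel)
        ct = ChoiceTrial(
            relation=rel,
            cue_object=cue,
            target_object=target,
            foil_object=foil,
            triplet_id=tid,
            foil_triplet_id=foil_tid,
            session=session,
            order_index=2 * pos,
        )
        choice_trials.append(ct)
        source_trials.append(
            SourceTrial(
                parent_choice=ct,
                correct_answer="indirect" if rel == "AC" else "direct",
                order_index=2 * pos + 1,
            )
        )
    return choice_trials, source_trials


def _keys_ac_first(
    triplet_ids: list[int],
    relations_of: dict[int, tuple[str, ...]],
    rng: np.random.Generator,
    base_key: dict[int, float] | None = None,
) -> dict[tuple[int, str], float]:
    """Uniform random order keys, repaired so AC gets the smallest key of its
    triplet (inference trials precede the corresponding AB/BC trials)."""
    keys: dict[tuple[int, str], float] = {}
    for tid in triplet_ids:
        rels = relations_of[tid]
        base = base_key.get(tid, 0.0) if base_key else 0.0
        vals = base + rng.uniform(0.0, 1.0, size=len(rels))
        if "AC" in rels:
            # stable repair: swap so the AC trial holds the minimum key
            i_ac = rels.index("AC")
            i_min = int(np.argmin(vals))
            vals[i_ac], vals[i_min] = vals[i_min], vals[i_ac]
        for rel, v in zip(rels, vals):
            keys[(tid, rel)] = float(v)
    return keys


def _encode_cycle_exp134(
    experiment_id: int,
    cycle_triplets: list[Triplet],
    session: int,
    rng: np.random.Generator,
    scene_pool: dict[str, list[str]] | None,
) -> list[EncodingTrial]:
    trials: list[EncodingTrial] = []
    ab_order = list(rng.permutation([t.triplet_id for t in cycle_triplets]))
    bc_order = list(rng.permutation([t.triplet_id for t in cycle_triplets]))
    scene_conditions: list[tuple[str, str]] = []
    if experiment_id == 3:
        # half of this session's BC trials preceded by novel, half by familiar
        half = len(bc_order) // 2
        novel = [scene_pool["novel"].pop() for _ in range(half)]
        familiar = [scene_pool["familiar"].pop() for _ in range(len(bc_order) - half)]
        scene_conditions = [("novel", s) for s in novel] + [
            ("familiar", s) for s in familiar
        ]
        perm = rng.permutation(len(scene_conditions))
        scene_conditions = [scene_conditions[i] for i in perm]
    pos = 0
    for tid in ab_order:
        trials.append(
            EncodingTrial(tid, "AB", session, int(rng.integers(2)), pos)
        )
        pos += 1
    for k, tid in enumerate(bc_order):
        cond, scene = scene_conditions[k] if scene_conditions else (None, None)
        trials.append(
            EncodingTrial(tid, "BC", session, int(rng.integers(2)), pos, cond, scene)
        )
        pos += 1
    return trials


def _encode_session_exp2(
    cycle_triplets: list[Triplet], session: int, rng: np.random.Generator
) -> list[EncodingTrial]:
    """Experiment-2 study session: every pair twice, AB block then BC block.

    BC presentations are ordered round-robin by the rank of each triplet's last
    AB presentation, which guarantees at least a 16-trial gap between any AB
    trial and its related BC trial (the stated minimum is 10).
    """
    ids = [t.triplet_id for t in cycle_triplets]
    ab_seq = list(rng.permutation(ids + ids))
    last_ab = {tid: max(i for i, x in enumerate(ab_seq) if x == tid) for tid in ids}
    ranked = sorted(ids, key=lambda tid: last_ab[tid])
    bc_seq = ranked + ranked  # two rounds in last-AB rank order
    trials = []
    pos = 0
    for tid in ab_seq:
        trials.append(EncodingTrial(tid, "AB", session, int(rng.integers(2)), pos))
        pos += 1
    for tid in bc_seq:
        trials.append(EncodingTrial(tid, "BC", session, int(rng.integers(2)), pos))
        pos += 1
    return trials


def build_schedule(experiment_id: int, seed: int) -> ExperimentSchedule:
    """Build the full trial program for one experiment variant.

    The construction is deterministic given ``seed``; randomization affects
    assignment and ordering only, never trial counts or the precedence
    constraints (inference trials before the corresponding AB/BC test trials,
    study-gap minimum in experiment 2, scene balance in experiment 3).
    """
    if experiment_id not in (1, 2, 3, 4):
        raise ValueError(f"unknown experiment_id {experiment_id!r}; expected 1-4")
    rng = np.random.default_rng(seed)
    triplets = _make_triplets()
    index_by_id = {t.triplet_id: t for t in triplets}

    # allocation of triplets into sessions is randomized
    perm = rng.permutation(len(triplets))
    sessions = [
        [triplets[i] for i in perm[s * TRIPLETS_PER_SESSION : (s + 1) * TRIPLETS_PER_SESSION]]
        for s in range(N_SESSIONS)
    ]
    session_of_triplet = {
        t.triplet_id: s + 1 for s, group in enumerate(sessions) for t in group
    }

    scene_pool = None
    familiar_scenes: list[str] = []
    novel_scenes: list[str] = []
    foil_scenes: list[str] = []
    if experiment_id == 3:
        familiar_scenes = [f"S{i}" for i in range(1, 41)]
        novel_scenes = [f"S{i}" for i in range(41, 81)]
        foil_scenes = [f"S{i}" for i in range(81, 101)]
        scene_pool = {
            "familiar": list(rng.permutation(familiar_scenes)),
            "novel": list(rng.permutation(novel_scenes)),
        }

    encoding: list[EncodingTrial] = []
    choice: list[ChoiceTrial] = []
    source: list[SourceTrial] = []

    if experiment_id in (1, 3, 4):
        for s, cycle in enumerate(sessions, start=1):
            encoding.extend(_encode_cycle_exp134(experiment_id, cycle, s, rng, scene_pool))
            ids = [t.triplet_id for t in cycle]
            if experiment_id == 4:
                relations_of = _exp4_relations(ids, rng)
            else:
                relations_of = {tid: RELATIONS for tid in ids}
            keys = _keys_ac_first(ids, relations_of, rng)
            if experiment_id == 4:
                keys = _exp4_balance_ab_bc(ids, relations_of, keys, rng)
            c, src = _build_test_block(cycle, s, rng, relations_of, keys, index_by_id)
            choice.extend(c)
            source.extend(src)
        pair_repetitions = 1
        structure = "study-test-cycles"
    else:  # experiment 2
        for s, cycle in enumerate(sessions, start=1):
            encoding.extend(_encode_session_exp2(cycle, s, rng))
        # single test block at the end; triplets interleaved round-robin across
        # study sessions to keep the study-test gap approximately equated
        rr: list[int] = []
        shuffled = [list(rng.permutation([t.triplet_id for t in g])) for g in sessions]
        for k in range(TRIPLETS_PER_SESSION):
            for g in shuffled:
                rr.append(int(g[k]))
        base_key = {tid: 3.0 * pos for pos, tid in enumerate(rr)}
        relations_of = {tid: RELATIONS for tid in rr}
        keys = _keys_ac_first(rr, relations_of, rng, base_key=None)
        # spread each triplet's trials near its round-robin position
        keys = {
            (tid, rel): base_key[tid] + 3.0 * v for (tid, rel), v in keys.items()
        }
        ordered_triplets = [index_by_id[tid] for tid in rr]
        c, src = _build_test_block(
            ordered_triplets, N_SESSIONS, rng, relations_of, keys, index_by_id
        )
        choice.extend(c)
        source.extend(src)
        pair_repetitions = 2
        structure = "all-study-then-test"

    return ExperimentSchedule(
        experiment_id=experiment_id,
        triplets=triplets,
        encoding_trials=encoding,
        choice_trials=choice,
        source_trials=source,
        pair_repetitions=pair_repetitions,
        cycle_structure=structure,
        session_of_triplet=session_of_triplet,
        familiar_scenes=familiar_scenes,
        novel_scenes=novel_scenes,
        foil_scenes=foil_scenes,
    )


def _exp4_relations(
    ids: list[int], rng: np.random.Generator
) -> dict[int, tuple[str, ...]]:
    """AC test trials omitted for exactly half of each cycle's triplets."""
    omitted = set(rng.choice(ids, size=len(ids) // 2, replace=False).tolist())
    return {
        tid: ("AB", "BC") if tid in omitted else RELATIONS for tid in ids
    }


def _exp4_balance_ab_bc(
    ids: list[int],
    relations_of: dict[int, tuple[str, ...]],
    keys: dict[tuple[int, str], float],
    rng: np.random.Generator,
) -> dict[tuple[int, str], float]:
    """Force AB-before-BC for half the triplets (and the reverse for the other
    half), balanced separately within AC-omitted and AC-tested triplets."""
    keys = dict(keys)
    for group_has_ac in (True, False):
        group = [tid for tid in ids if ("AC" in relations_of[tid]) == group_has_ac]
        ab_first = set(rng.choice(group, size=len(group) // 2, replace=False).tolist())
        for tid in group:
            ka, kb = keys[(tid, "AB")], keys[(tid, "BC")]
            lo, hi = min(ka, kb), max(ka, kb)
            if tid in ab_first:
                keys[(tid, "AB")], keys[(tid, "BC")] = lo, hi
            else:
                keys[(tid, "AB")], keys[(tid, "BC")] = hi, lo
    return keys


# ---------------------------------------------------------------------------
# validation

def validate_schedule(schedule: ExperimentSchedule) -> list[str]:
    """Check every schedule invariant; return human-readable violations.

    Validation never raises: a structurally broken schedule yields descriptors
    naming the offending trials.
    """
    v: list[str] = []
    exp = schedule.experiment_id
    ids = {t.triplet_id for t in schedule.triplets}

    seen_objects: dict[str, int] = {}
    for t in schedule.triplets:
        objs = t.objects()
        if len(set(objs)) != 3:
            v.append(f"triplet {t.triplet_id}: objects not distinct")
        for o in objs:
            if o in seen_objects:
                v.append(
                    f"object {o} shared by triplets {seen_objects[o]} and {t.triplet_id}"
                )
            seen_objects[o] = t.triplet_id

    # encoding invariants
    reps: dict[tuple[int, str], int] = {}
    for e in schedule.encoding_trials:
        if e.pair_kind not in PAIR_KINDS:
            v.append(f"encoding trial of triplet {e.triplet_id}: bad pair kind {e.pair_kind}")
        has_scene = e.preceding_scene is not None
        should_have = exp == 3 and e.pair_kind == "BC"
        if has_scene != should_have:
            v.append(
                f"encoding trial triplet {e.triplet_id} {e.pair_kind} session {e.session}: "
                f"preceding_scene {'present' if has_scene else 'missing'}"
            )
        reps[(e.triplet_id, e.pair_kind)] = reps.get((e.triplet_id, e.pair_kind), 0) + 1
    want_reps = schedule.pair_repetitions
    for tid in ids:
        for kind in PAIR_KINDS:
            n = reps.get((tid, kind), 0)
            if n != want_reps:
                v.append(f"pair {kind} of triplet {tid} presented {n}x (expected {want_reps})")

    # choice-trial invariants
    expected_choice = {1: 240, 2: 240, 3: 240, 4: 200}[exp]
    if len(schedule.choice_trials) != expected_choice:
        v.append(
            f"{len(schedule.choice_trials)} choice trials (expected {expected_choice})"
        )
    index = {t.triplet_id: t for t in schedule.triplets}
    for c in schedule.choice_trials:
        trip = index.get(c.triplet_id)
        if trip is None:
            v.append(f"choice trial references unknown triplet {c.triplet_id}")
            continue
        cue, target = _cue_target(trip, c.relation)
        if (c.cue_object, c.target_object) != (cue, target):
            v.append(
                f"choice {c.relation} triplet {c.triplet_id}: cue/target not from triplet"
            )
        if c.foil_triplet_id == c.triplet_id or c.foil_object in trip.objects():
            v.append(f"choice {c.relation} triplet {c.triplet_id}: foil from same triplet")

    # source-trial invariants
    if len(schedule.source_trials) != len(schedule.choice_trials):
        v.append(
            f"{len(schedule.source_trials)} source trials for "
            f"{len(schedule.choice_trials)} choice trials"
        )
    parents = {id(s.parent_choice) for s in schedule.source_trials}
    if len(parents) != len(schedule.source_trials):
        v.append("source trials share a parent choice trial")
    for s in schedule.source_trials:
        want = "indirect" if s.parent_choice.relation == "AC" else "direct"
        if s.correct_answer != want:
            v.append(
                f"source trial for {s.parent_choice.relation} triplet "
                f"{s.parent_choice.triplet_id}: correct_answer {s.correct_answer}"
            )

    # AC trials precede the corresponding AB/BC test trials (within session)
    order: dict[tuple[int, int, str], int] = {}
    for c in schedule.choice_trials:
        order[(c.session, c.triplet_id, c.relation)] = c.order_index
    for (sess, tid, rel), oi in order.items():
        if rel == "AC":
            for other in ("AB", "BC"):
                oo = order.get((sess, tid, other))
                if oo is not None and oo < oi:
                    v.append(
                        f"triplet {tid} session {sess}: {other} test at {oo} precedes AC at {oi}"
                    )

    if exp == 2:
        v.extend(_validate_exp2_gap(schedule))
    if exp == 3:
        v.extend(_validate_exp3_scenes(schedule))
    if exp == 4:
        v.extend(_validate_exp4(schedule, order))
    return v


def _validate_exp2_gap(schedule: ExperimentSchedule) -> list[str]:
    v = []
    by_session: dict[int, list[EncodingTrial]] = {}
    for e in schedule.encoding_trials:
        by_session.setdefault(e.session, []).append(e)
    for sess, trials in by_session.items():
        pos = {("AB", t.triplet_id): [] for t in schedule.triplets}
        pos.update({("BC", t.triplet_id): [] for t in schedule.triplets})
        for e in trials:
            pos[(e.pair_kind, e.triplet_id)].append(e.order_index)
        for t in schedule.triplets:
            abs_, bcs = pos[("AB", t.triplet_id)], pos[("BC", t.triplet_id)]
            if not abs_ or not bcs:
                continue
            gap = min(bcs) - max(abs_)
            if gap < MIN_AB_BC_GAP:
                v.append(
                    f"triplet {t.triplet_id} session {sess}: AB-BC study gap {gap} < {MIN_AB_BC_GAP}"
                )
    return v


def _validate_exp3_scenes(schedule: ExperimentSchedule) -> list[str]:
    v = []
    by_session: dict[int, list[str]] = {}
    for e in schedule.encoding_trials:
        if e.pair_kind == "BC":
            by_session.setdefault(e.session, []).append(e.preceding_scene)
    for sess, conds in by_session.items():
        n_novel = sum(c == "novel" for c in conds)
        n_fam = sum(c == "familiar" for c in conds)
        if n_novel != len(conds) // 2 or n_fam != len(conds) - len(conds) // 2:
            v.append(f"session {sess}: scene split novel={n_novel} familiar={n_fam}")
    return v


def _validate_exp4(
    schedule: ExperimentSchedule, order: dict[tuple[int, int, str], int]
) -> list[str]:
    v = []
    tested = {c.triplet_id for c in schedule.choice_trials if c.relation == "AC"}
    all_ids = {t.triplet_id for t in schedule.triplets}
    if len(tested) != len(all_ids) // 2:
        v.append(f"AC tested for {len(tested)} triplets (expected {len(all_ids) // 2})")
    for has_ac in (True, False):
        group = [tid for tid in all_ids if (tid in tested) == has_ac]
        ab_first = 0
        for tid in group:
            sess = schedule.session_of_triplet[tid]
            if order[(sess, tid, "AB")] < order[(sess, tid, "BC")]:
                ab_first += 1
        if abs(ab_first - len(group) / 2) > 0.5:
            v.append(
                f"AB-before-BC for {ab_first}/{len(group)} "
                f"{'AC-tested' if has_ac else 'AC-omitted'} triplets (expected half)"
            )
    return v


# ---------------------------------------------------------------------------
# serialization

def schedule_to_frame(schedule: ExperimentSchedule) -> pd.DataFrame:
    """One row per trial: encoding rows first, then the interleaved test rows,
    ordered by session then order_index (deterministic)."""
    rows = []
    for e in schedule.encoding_trials:
        trip = schedule.triplet_by_id(e.triplet_id)
        a, b = trip.pair(e.pair_kind)
        rows.append(
            dict(
                experiment=schedule.experiment_id,
                phase="encoding",
                session=e.session,
                order_index=e.order_index,
                relation=e.pair_kind,
                triplet_id=e.triplet_id,
                cue=a,
                target=b,
                foil="",
                scene_condition=e.preceding_scene or "",
            )
        )
    for c in schedule.choice_trials:
        rows.append(
            dict(
                experiment=schedule.experiment_id,
                phase="choice",
                session=c.session,
                order_index=c.order_index,
                relation=c.relation,
                triplet_id=c.triplet_id,
                cue=c.cue_object,
                target=c.target_object,
                foil=c.foil_object,
                scene_condition="",
            )
        )
    for s in schedule.source_trials:
        c = s.parent_choice
        rows.append(
            dict(
                experiment=schedule.experiment_id,
                phase="source",
                session=c.session,
                order_index=s.order_index,
                relation=c.relation,
                triplet_id=c.triplet_id,
                cue=c.cue_object,
                target=c.target_object,
                foil=c.foil_object,
                scene_condition="",
            )
        )
    frame = pd.DataFrame(rows)
    phase_rank = {"encoding": 0, "choice": 1, "source": 1}
    frame["_rank"] = frame["phase"].map(phase_rank)
    frame = frame.sort_values(["session", "_rank", "order_index"], kind="stable")
    return frame.drop(columns="_rank").reset_index(drop=True)


def write_schedule_csv(schedule: ExperimentSchedule, path) -> None:
    schedule_to_frame(schedule).to_csv(path, index=False, encoding="utf-8")
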