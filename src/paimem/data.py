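"""Behavioral dataset schema and trial-exclusion rules.

A behavioral dataset is a tidy table with one row per *test* trial:

======================  =====================================================
column                  meaning
======================  =====================================================
subject                 subject identifier (integer)
experiment              experiment variant 1-4
session                 session/cycle in which the trial occurred
phase                   ``choice`` or ``source``
relation                ``AB``, ``BC`` or ``AC``
triplet_id              triplet probed by the trial
response                ``target``/``foil`` (choice), ``direct``/``indirect``
                        (source); empty for a timeout
correct                 whether the response was correct (boolean)
rt_seconds              response time, NaN for timeouts
scene_condition         ``novel``/``familiar`` for experiment-3 triplets
scene_recognized        whether the novel scene was later recognized
======================  =====================================================

A source row's parent is the choice row with the same (subject, session,
triplet, relation).  Source trials are analyzed only when the parent choice
was correct: an "indirect"/"direct" judgment about a pair the participant got
wrong concerns a pair that was never probed as intended.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DATASET_COLUMNS",
    "PARENT_KEY",
    "exclude_source_trials",
    "apply_source_exclusion",
    "drop_timeouts",
    "write_dataset_csv",
    "read_dataset_csv",
]

DATASET_COLUMNS = [
    "subject",
    "experiment",
    "session",
    "phase",
    "relation",
    "triplet_id",
    "response",
    "correct",
    "rt_seconds",
    "scene_condition",
    "scene_recognized",
]

PARENT_KEY = ["subject", "session", "triplet_id", "relation"]


def exclude_source_trials(dataset: pd.DataFrame) -> pd.DataFrame:
    """Drop source rows whose parent choice was not answered correctly.

    Choice rows pass through untouched.  A source row without a matching
    choice row (dangling parent link) is rejected.
    """
    choice = dataset[dataset["phase"] == "choice"]
    source = dataset[dataset["phase"] == "source"]
    parent_correct = choice.set_index(PARENT_KEY)["correct"]
    if not parent_correct.index.is_unique:
        raise ValueError("choice rows are not unique on " + ", ".join(PARENT_KEY))
    key = pd.MultiIndex.from_frame(source[PARENT_KEY])
    matched = key.isin(parent_correct.index)
    if not matched.all():
        bad = source[~matched].iloc[0]
        raise ValueError(
            "source trial has no parent choice row: subject "
            f"{bad['subject']}, triplet {bad['triplet_id']}, {bad['relation']}"
        )
    keep = parent_correct.reindex(key).to_numpy().astype(bool)
    out = pd.concat([choice, source[keep]])
    return out.sort_index()


def apply_source_exclusion(dataset: pd.DataFrame) -> pd.DataFrame:
    """Alias used by the fitting/analysis layers."""
    return exclude_source_trials(dataset)


def drop_timeouts(dataset: pd.DataFrame) -> pd.DataFrame:
    """Remove trials without a response."""
    resp = dataset["response"]
    mask = resp.notna() & (resp != "")
    return dataset[mask]


def write_dataset_csv(dataset: pd.DataFrame, path) -> None:
    out = dataset.reindex(columns=DATASET_COLUMNS)
    out.to_csv(path, index=False, encoding="utf-8", na_rep="")


def read_dataset_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(
        path,
        dtype={"response": "string", "scene_condition": "string"},
        keep_default_na=True,
    )
    frame["response"] = frame["response"].fillna("")
    frame["scene_condition"] = frame["scene_condition"].fillna("")
    frame["correct"] = frame["correct"].astype(bool)
    if "scene_recognized" in frame:
        frame["scene_recognized"] = frame["scene_recognized"].astype("boolean")
    return frame
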