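"""Trial-level data model, I/O and filtering for same-different experiments.

A trial log is a delimited text table (comma default, tab accepted) with one
row per behavioral response:

    participant_id, session_index, phase, trial_index,
    encoding_duration_ms, pair_type, response, response_time_s

``response`` may be ``none`` for an omitted response (no keypress); an
omitted response is never scored as correct.  The :class:`TrialTable`
wrapper keeps the rows in a :class:`pandas.DataFrame` together with a
provenance map (source path, applied filters, generator seed) so every
downstream number can be traced back to its inputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "PAIR_TYPES",
    "RESPONSES",
    "DEFAULT_SESSION_SCHEDULE",
    "TRAINING_SESSIONS",
    "EVALUATION_SESSIONS",
    "GENERALIZATION_SESSIONS",
    "EVALUATION_DURATIONS_MS",
    "TRAINING_DURATION_MS",
    "COLUMNS",
    "Trial",
    "TrialTable",
    "SessionSpec",
    "FilterReport",
    "InclusionReport",
    "TrialFormatError",
    "TrialValueError",
    "read_trials",
    "write_trials",
    "filter_by_rt",
    "apply_inclusion_criterion",
    "summarize_counts",
]

PHASES = ("training", "evaluation", "generalization")
PAIR_TYPES = ("same", "different")
RESPONSES = ("same", "different", "none")

#: 11-session schedule: six training sessions interleaved with four
#: evaluation sessions, then one generalization session with novel stimuli.
TRAINING_SESSIONS = (2, 3, 5, 6, 8, 9)
EVALUATION_SESSIONS = (1, 4, 7, 10)
GENERALIZATION_SESSIONS = (11,)
DEFAULT_SESSION_SCHEDULE: Mapping[int, str] = {
    **{s: "training" for s in TRAINING_SESSIONS},
    **{s: "evaluation" for s in EVALUATION_SESSIONS},
    **{s: "generalization" for s in GENERALIZATION_SESSIONS},
}

#: The eight first-stimulus encoding durations used in evaluation and
#: generalization sessions (multiples of a 60 Hz frame), and the fixed
#: training duration.
EVALUATION_DURATIONS_MS = (17, 50, 84, 117, 150, 234, 500, 1000)
TRAINING_DURATION_MS = 100

#: Mandatory columns of a trial log, in canonical order.
COLUMNS = (
    "participant_id",
    "session_index",
    "phase",
    "trial_index",
    "encoding_duration_ms",
    "pair_type",
    "response",
    "response_time_s",
)

#: Duration of the backward mask that terminates encoding of the first
#: stimulus; SOA = encoding duration + mask duration.
BACKWARD_MASK_S = 0.5


class TrialFormatError(ValueError):
    """A trial log violates the file-level contract (e.g. missing column)."""


class TrialValueError(ValueError):
    """A trial log row carries an unparsable or invariant-violating value."""


@dataclass(frozen=True)
class Trial:
    """One behavioral response with its timing and design labels."""

    participant_id: str
    session_index: int
    phase: str
    trial_index: int
    encoding_duration_ms: float
    pair_type: str
    response: str
    response_time_s: float

    @property
    def correct(self) -> bool:
        """True iff the response matches the pair type (never for ``none``)."""
        return self.response != "none" and self.response == self.pair_type


@dataclass
class SessionSpec:
    """Design of one session: trial counts per duration, 1:1 same/different."""

    phase: str
    durations_ms: Sequence[float]
    trials_per_duration: int

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.trials_per_duration <= 0 or self.trials_per_duration % 2:
            raise ValueError("trials_per_duration must be positive and even "
                             "(equal same/different counts)")

    @property
    def n_trials(self) -> int:
        return self.trials_per_duration * len(self.durations_ms)

    def soa_s(self, duration_ms: float) -> float:
        """Stimulus onset asynchrony: encoding duration plus backward mask."""
        return duration_ms / 1000.0 + BACKWARD_MASK_S

    @classmethod
    def training(cls) -> "SessionSpec":
        # 360 trials at a fixed 100 ms encoding duration
        return cls("training", [TRAINING_DURATION_MS], 360)

    @classmethod
    def evaluation(cls) -> "SessionSpec":
        # 480 trials: 60 per duration, 30 same / 30 different
        return cls("evaluation", list(EVALUATION_DURATIONS_MS), 60)

    @classmethod
    def generalization(cls) -> "SessionSpec":
        spec = cls.evaluation()
        spec.phase = "generalization"
        return spec


class TrialTable:
    """Ordered collection of trials backed by a :class:`pandas.DataFrame`.

    ``meta`` records provenance: ``source`` path for data read from disk,
    ``seed`` for synthetic data, and an append-only ``filters`` history.
    """

    def __init__(self, frame: pd.DataFrame, meta: dict | None = None) -> None:
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise TrialFormatError(f"missing mandatory column(s): {', '.join(missing)}")
        frame = frame.reset_index(drop=True)
        _validate_frame(frame)
        self.frame = frame
        self.meta = dict(meta or {})
        self.meta.setdefault("filters", [])
        key = frame[["participant_id", "session_index", "trial_index"]]
        if key.duplicated().any():
            raise TrialValueError(
                "(participant_id, session_index, trial_index) must be unique")

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterable[Trial]:
        for row in self.frame.itertuples(index=False):
            yield Trial(
                participant_id=str(row.participant_id),
                session_index=int(row.session_index),
                phase=str(row.phase),
                trial_index=int(row.trial_index),
                encoding_duration_ms=float(row.encoding_duration_ms),
                pair_type=str(row.pair_type),
                response=str(row.response),
                response_time_s=float(row.response_time_s),
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        return self.frame[list(COLUMNS)].equals(other.frame[list(COLUMNS)])

    @property
    def correct(self) -> pd.Series:
        """Derived correctness flag; omissions are always incorrect."""
        f = self.frame
        return (f["response"] != "none") & (f["response"] == f["pair_type"])

    def subset(self, mask: pd.Series, note: str) -> "TrialTable":
        meta = dict(self.meta)
        meta["filters"] = list(self.meta["filters"]) + [note]
        return TrialTable(self.frame.loc[mask].reset_index(drop=True), meta)

    @classmethod
    def from_trials(cls, trials: Iterable[Trial], meta: dict | None = None) -> "TrialTable":
        rows = [{c: getattr(t, c) for c in COLUMNS} for t in trials]
        return cls(pd.DataFrame(rows, columns=list(COLUMNS)), meta)


def _validate_frame(frame: pd.DataFrame) -> None:
    for col, allowed in (("phase", PHASES), ("pair_type", PAIR_TYPES),
                         ("response", RESPONSES)):
        bad = ~frame[col].isin(allowed)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise TrialValueError(
                f"row {i + 1}: invalid {col} {frame[col].iloc[i]!r}")
    for col, lo in (("response_time_s", 0.0), ("encoding_duration_ms", 0.0),
                    ("trial_index", 1), ("session_index", 1)):
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = vals.isna() | (vals < lo)
        if col == "encoding_duration_ms":
            bad |= vals <= 0
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise TrialValueError(
                f"row {i + 1}: invalid {col} {frame[col].iloc[i]!r}")


def read_trials(path: str | Path, dialect: str = "auto") -> TrialTable:
    """Read a delimited trial log into a :class:`TrialTable`.

    ``dialect`` is ``"csv"``, ``"tsv"`` or ``"auto"`` (sniff the header
    line).  Unknown extra columns are preserved in ``meta["extra_columns"]``
    and kept on the frame; row order is preserved.
    """
    path = Path(path)
    if dialect == "auto":
        header = path.open(encoding="utf-8").readline()
        dialect = "tsv" if "\t" in header else "csv"
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    frame = pd.read_csv(path, sep=sep, dtype={"participant_id": str})
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise TrialFormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}")
    extra = [c for c in frame.columns if c not in COLUMNS]
    table = TrialTable(frame, meta={"source": str(path)})
    if extra:
        table.meta["extra_columns"] = extra
    return table


def write_trials(table: TrialTable, path: str | Path, dialect: str = "csv") -> None:
    """Write a trial log; inverse of :func:`read_trials`."""
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    cols = list(COLUMNS) + [c for c in table.frame.columns if c not in COLUMNS]
    table.frame[cols].to_csv(path, sep=sep, index=False)


@dataclass
class FilterReport:
    """Kept/removed trial counts per participant x session for one filter."""

    name: str
    counts: pd.DataFrame  # columns: participant_id, session_index, kept, removed
    params: dict = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return int(self.counts["kept"].sum())

    @property
    def n_removed(self) -> int:
        return int(self.counts["removed"].sum())

    def to_json(self) -> str:
        return json.dumps({
            "filter": self.name,
            "params": self.params,
            "n_kept": self.n_kept,
            "n_removed": self.n_removed,
            "cells": self.counts.to_dict(orient="records"),
        }, indent=2)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)


def filter_by_rt(table: TrialTable, lo_s: float = 0.2, hi_s: float = 5.0
                 ) -> tuple[TrialTable, FilterReport]:
    """Keep trials with response time in the closed interval [lo_s, hi_s].

    The window endpoints are inclusive so that responses exactly at the
    5.0 s deadline remain analyzable.  Returns the filtered table and a
    per-participant, per-session report; kept + removed always equals the
    input count.
    """
    if not lo_s < hi_s:
        raise ValueError("lo_s must be < hi_s")
    rt = table.frame["response_time_s"]
    keep = (rt >= lo_s) & (rt <= hi_s)
    if len(table):
        counts = (
            table.frame.assign(kept=keep)
            .groupby(["participant_id", "session_index"], sort=True)["kept"]
            .agg(kept="sum", removed=lambda s: int((~s).sum()))
            .reset_index()
        )
        counts["kept"] = counts["kept"].astype(int)
        counts["removed"] = counts["removed"].astype(int)
    else:
        counts = pd.DataFrame(columns=["participant_id", "session_index",
                                       "kept", "removed"])
    report = FilterReport("rt_window", counts, {"lo_s": lo_s, "hi_s": hi_s})
    kept = table.subset(keep, f"rt_window[{lo_s},{hi_s}]")
    return kept, report


@dataclass
class InclusionReport:
    """Outcome of the minimum-learning inclusion rule per participant."""

    included: list
    excluded: list
    undetermined: list
    deltas: dict
    params: dict

    def to_json(self) -> str:
        return json.dumps({
            "included": self.included, "excluded": self.excluded,
            "undetermined": self.undetermined, "deltas": self.deltas,
            "params": self.params,
        }, indent=2)


def apply_inclusion_criterion(
    dprime_by_session: Mapping[str, Mapping[int, float]],
    delta_min: float = 0.4,
    baseline_session: int = 1,
    criterion_session: int = 8,
) -> InclusionReport:
    """Include participants whose sensitivity improved by at least ``delta_min``.

    A participant is included iff d'(criterion_session) - d'(baseline_session)
    >= delta_min (the comparison is inclusive).  Participants missing either
    session are flagged ``undetermined`` and belong to neither list.
    """
    included, excluded, undetermined, deltas = [], [], [], {}
    for pid, by_session in dprime_by_session.items():
        if baseline_session not in by_session or criterion_session not in by_session:
            undetermined.append(pid)
            continue
        delta = by_session[criterion_session] - by_session[baseline_session]
        deltas[pid] = delta
        # inclusive >=, robust to float representation of the difference
        passes = delta >= delta_min or math.isclose(delta, delta_min,
                                                    rel_tol=1e-9, abs_tol=1e-12)
        (included if passes else excluded).append(pid)
    return InclusionReport(
        included, excluded, undetermined, deltas,
        {"delta_min": delta_min, "baseline_session": baseline_session,
         "criterion_session": criterion_session})


def summarize_counts(table: TrialTable, grouping: Sequence[str]) -> pd.DataFrame:
    """Tally hit / false-alarm / omission counts per analysis cell.

    With "different" pairs as the signal class, a hit is a "different"
    response to a different pair and a false alarm a "different" response
    to a same pair.  Omitted responses are counted in ``n_omit`` and enter
    neither the hit nor false-alarm tallies.  Cell counts sum to the input
    trial count.
    """
    for g in grouping:
        if g not in table.frame.columns:
            raise KeyError(f"grouping field {g!r} not a trial field")
    f = table.frame
    responded = f["response"] != "none"
    tall = pd.DataFrame({
        "n_different_trials": ((f["pair_type"] == "different") & responded),
        "n_same_trials": ((f["pair_type"] == "same") & responded),
        "n_hit": ((f["pair_type"] == "different")
                  & (f["response"] == "different")),
        "n_fa": ((f["pair_type"] == "same")
                 & (f["response"] == "different")),
        "n_omit": ~responded,
    })
    for g in grouping:
        tall[g] = f[g]
    out = tall.groupby(list(grouping), sort=True).sum().reset_index()
    count_cols = ["n_different_trials", "n_same_trials", "n_hit", "n_fa", "n_omit"]
    out[count_cols] = out[count_cols].astype(int)
    return out
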