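"""Bout-level hypnogram ingestion and normalization.

A hypnogram here is a time-ordered, gap-free partition of a wear period into
sleep and wake intervals ("bouts"), as produced by an upstream sleep/wake
classifier.  Bouts covering nonwear time arrive with an imputed probability
of sleep instead of a hard state; :func:`resolve_imputed` turns these into
definite states while keeping the imputed flag for downstream data-quality
filters.

All intervals are half-open ``[start, end)`` so that abutting bouts never
double-count an instant.  Timestamps are timezone-naive local clock time;
recordings spanning a daylight-saving transition are expected to be excluded
upstream, so no DST arithmetic is performed anywhere in this package.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

MAX_RECORDING_DAYS = 8  # 7-day wear protocol plus slack


class State(enum.Enum):
    SLEEP = "sleep"
    WAKE = "wake"


@dataclass(frozen=True)
class Bout:
    """One contiguous sleep or wake interval, half-open ``[start, end)``.

    ``state`` may be ``None`` only for an unresolved imputed bout, in which
    case ``p_sleep`` must be set.
    """

    start: datetime
    end: datetime
    state: State | None
    imputed: bool = False
    p_sleep: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"bout has non-positive duration: {self.start} .. {self.end}")
        if self.state is None and self.p_sleep is None:
            raise ValueError("bout with no state must carry p_sleep")
        if self.p_sleep is not None and not (0.0 <= self.p_sleep <= 1.0):
            raise ValueError(f"p_sleep out of [0, 1]: {self.p_sleep}")

    @property
    def duration_minutes(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


@dataclass
class Recording:
    """A participant's full bout sequence tiling ``[recording_start, recording_end)``."""

    participant_id: str
    bouts: list[Bout] = field(default_factory=list)

    @property
    def recording_start(self) -> datetime:
        return self.bouts[0].start

    @property
    def recording_end(self) -> datetime:
        return self.bouts[-1].end

    def validate(self) -> None:
        """Check ordering, tiling and span invariants; raise ``ValueError`` on violation."""
        if not self.bouts:
            raise ValueError(f"{self.participant_id}: empty recording")
        for prev, cur in zip(self.bouts, self.bouts[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"{self.participant_id}: overlapping bouts at {cur.start}"
                )
            if cur.start > prev.end:
                raise ValueError(
                    f"{self.participant_id}: gap in tiling "
                    f"[{prev.end} .. {cur.start})"
                )
        span = self.recording_end - self.recording_start
        if span > timedelta(days=MAX_RECORDING_DAYS):
            raise ValueError(
                f"{self.participant_id}: recording span {span} exceeds "
                f"{MAX_RECORDING_DAYS} days"
            )

    def total_minutes(self, state: State) -> float:
        return sum(b.duration_minutes for b in self.bouts if b.state is state)


# ---------------------------------------------------------------------------
# reading / writing


_BOUT_COLUMNS = ["participant_id", "start", "end", "state", "imputed", "p_sleep"]


def _parse_bout_row(row: pd.Series, rownum: int) -> tuple[str, Bout]:
    try:
        start = datetime.fromisoformat(str(row["start"]))
        end = datetime.fromisoformat(str(row["end"]))
        imputed = bool(int(row["imputed"]))
        raw_state = row.get("state")
        state_str = "" if pd.isna(raw_state) else str(raw_state).strip().lower()
        raw_p = row.get("p_sleep")
        p_sleep = None if pd.isna(raw_p) or raw_p == "" else float(raw_p)
        state = State(state_str) if state_str else None
        return str(row["participant_id"]), Bout(start, end, state, imputed, p_sleep)
    except (ValueError, KeyError, TypeError) as exc:
        raise ValueError(f"unparseable bout row {rownum}: {exc}") from exc


def read_bout_table(
    path: str | Path,
    dialect: str = "bout",
    epoch_minutes: float | None = None,
) -> tuple[list[Recording], dict[str, str]]:
    """Read a bout CSV into one :class:`Recording` per participant.

    Two dialects are accepted.  ``"bout"`` is one row per interval with
    columns ``participant_id, start, end, state, imputed, p_sleep`` (state
    empty iff the bout is imputed with ``p_sleep`` set).  ``"epoch"`` is one
    row per fixed-width epoch with columns ``participant_id, start, state,
    imputed, p_sleep``; ``epoch_minutes`` declares the epoch length and runs
    of identical epochs are merged into bouts on load.

    A participant whose intervals overlap or leave gaps is dropped with a
    logged diagnostic rather than aborting the batch; an unparseable row is a
    hard error naming the row number.  Returns ``(recordings, rejected)``
    where ``rejected`` maps participant id to the reason for rejection.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    if dialect == "epoch":
        if epoch_minutes is None:
            raise ValueError("epoch dialect requires epoch_minutes")
        df = df.copy()
        df["end"] = [
            (datetime.fromisoformat(s) + timedelta(minutes=epoch_minutes)).isoformat()
            for s in df["start"]
        ]
    elif dialect != "bout":
        raise ValueError(f"unknown dialect: {dialect!r}")

    per_participant: dict[str, list[Bout]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        pid, bout = _parse_bout_row(pd.Series(row._asdict()), rownum=i + 2)
        per_participant.setdefault(pid, []).append(bout)

    recordings: list[Recording] = []
    rejected: dict[str, str] = {}
    for pid, bouts in per_participant.items():
        bouts.sort(key=lambda b: (b.start, b.end))
        rec = Recording(pid, bouts)
        try:
            rec.validate()
        except ValueError as exc:
            logger.warning("rejecting participant %s: %s", pid, exc)
            rejected[pid] = str(exc)
            continue
        recordings.append(rec)
    return recordings, rejected


def write_bout_table(recordings: Iterable[Recording], path: str | Path) -> None:
    """Write recordings back to the bout CSV dialect (inverse of :func:`read_bout_table`)."""
    rows = []
    for rec in recordings:
        for b in rec.bouts:
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "start": b.start.isoformat(timespec="seconds"),
                    "end": b.end.isoformat(timespec="seconds"),
                    "state": "" if b.state is None else b.state.value,
                    "imputed": int(b.imputed),
                    "p_sleep": "" if b.p_sleep is None else b.p_sleep,
                }
            )
    pd.DataFrame(rows, columns=_BOUT_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# normalization


def resolve_imputed(rec: Recording, threshold: float = 0.5) -> Recording:
    """Assign definite states to imputed bouts.

    An imputed bout becomes SLEEP when its imputed probability of sleep is
    strictly greater than ``threshold`` (default 0.5) and WAKE otherwise.
    The imputed flag is preserved so the day-level imputed-fraction filter
    still sees which time was imputed.
    """
    out = []
    for b in rec.bouts:
        if b.imputed:
            if b.p_sleep is None:
                raise ValueError(
                    f"{rec.participant_id}: imputed bout at {b.start} lacks p_sleep"
                )
            state = State.SLEEP if b.p_sleep > threshold else State.WAKE
            out.append(replace(b, state=state))
        else:
            out.append(b)
    return Recording(rec.participant_id, out)


def normalize(rec: Recording) -> Recording:
    """Merge adjacent bouts sharing both state and imputed flag.

    Requires definite states (run :func:`resolve_imputed` first).  Raises on
    any gap in the tiling, naming the gap interval.  Idempotent.
    """
    merged: list[Bout] = []
    for b in rec.bouts:
        if b.state is None:
            raise ValueError(f"{rec.participant_id}: unresolved imputed bout at {b.start}")
        if merged:
            prev = merged[-1]
            if b.start > prev.end:
                raise ValueError(
                    f"{rec.participant_id}: gap in tiling [{prev.end} .. {b.start})"
                )
            if prev.state is b.state and prev.imputed == b.imputed:
                merged[-1] = replace(prev, end=b.end, p_sleep=None if prev.p_sleep is None else prev.p_sleep)
                continue
        merged.append(b)
    return Recording(rec.participant_id, merged)


def state_runs(bouts: Sequence[Bout]) -> list[tuple[datetime, datetime, State]]:
    """Coalesce a bout sequence into maximal same-state runs, ignoring the imputed flag.

    Sleep-period detection and the derived measures operate on physiological
    state alone; whether part of a run was imputed matters only for the
    imputed-fraction filter.
    """
    runs: list[tuple[datetime, datetime, State]] = []
    for b in bouts:
        if b.state is None:
            raise ValueError("state_runs requires resolved states")
        if runs and runs[-1][2] is b.state and runs[-1][1] == b.start:
            runs[-1] = (runs[-1][0], b.end, b.state)
        else:
            runs.append((b.start, b.end, b.state))
    return runs
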