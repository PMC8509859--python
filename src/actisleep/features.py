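"""Day segmentation, primary-sleep-period detection, and the 10 sleep measures.

Each recording is cut into 3 PM -> 3 PM "days".  Within each day the primary
sleep period (PSP) is the longest time span containing sleep bouts of at
least 30 minutes separated by gaps of no more than 60 minutes: sleep runs of
>= ``anchor_minutes`` are "anchors", consecutive anchors are chained while
the time from one anchor's end to the next anchor's start is <=
``gap_minutes``, each maximal chain spans from its first anchor's start to
its last anchor's end, and the PSP is the chain with the longest span (ties
broken by earliest onset).  Short sleep bouts inside a chain do not extend
it but do count as sleep once inside the PSP.

Days are invalid when no sleep run of >= 30 minutes touches the day, when
the PSP crosses a 3 PM boundary, or when more than 10% of the day's 1,440
minutes were imputed.  Participant-level measures are medians (or unscaled
median absolute deviations, for the two variability measures) across valid
days; participants with fewer than 2 valid days, or whose median wake-up
time falls in the afternoon, are excluded.

The 10 measures and their units:

==========================  =======================================================
bedtime                     hours since midnight of the day the window opens
wakeup_time                 hours since the same midnight (>24 = past midnight)
sleep_duration              hours of sleep inside the PSP
waso                        minutes of wake inside the PSP (wake after sleep onset)
sleep_efficiency            fraction of the PSP spent asleep, 1 - WASO/span
n_awakenings                count of wake runs strictly inside the PSP
longest_sleep_bout          hours, longest maximal sleep run inside the PSP
n_naps                      count of >30-minute sleep runs outside the PSP
bedtime_variability         hours, MAD of bedtime across valid days
sleep_duration_variability  hours, MAD of sleep duration across valid days
==========================  =======================================================
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import datetime, time, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hypnogram import Bout, Recording, State, state_runs

DAY_START_HOUR = 15          # days run 3 PM -> 3 PM
ANCHOR_MINUTES = 30.0        # minimum sleep-bout length to anchor the PSP
GAP_MINUTES = 60.0           # maximum anchor-to-anchor gap inside a PSP
NAP_MINUTES = 30.0           # naps must be strictly longer than this
IMPUTED_MAX_FRACTION = 0.10  # day invalid above this imputed fraction
MIN_VALID_DAYS = 2
AFTERNOON_WAKEUP_H = 36.0    # noon of the post-midnight day, in hours since reference midnight
BOUNDARY_MARGIN_H = 6.0      # context either side of a day used for PSP detection

Run = tuple[float, float, bool]  # (start_min, end_min, is_sleep), minutes on an arbitrary origin


class InvalidReason(enum.Enum):
    NONE = "none"
    NO_QUALIFYING_SLEEP = "no_qualifying_sleep"
    PSP_CROSSES_BOUNDARY = "psp_crosses_boundary"
    IMPUTED_GT_10PCT = "imputed_gt_10pct"
    PARTIAL_COVERAGE = "partial_coverage"


@dataclass(frozen=True)
class DayWindow:
    day_index: int
    window_start: datetime  # 15:00 local
    window_end: datetime    # 15:00 next day
    complete: bool          # recording covers the full 24 h

    @property
    def reference_midnight(self) -> datetime:
        return datetime.combine(self.window_start.date(), time(0))


@dataclass(frozen=True)
class PrimarySleepPeriod:
    onset_min: float
    offset_min: float
    sleep_minutes: float
    waso_minutes: float
    n_awakenings: int
    longest_sleep_bout_minutes: float

    @property
    def span_minutes(self) -> float:
        return self.offset_min - self.onset_min


@dataclass
class DaySummary:
    day: DayWindow
    psp: PrimarySleepPeriod | None
    valid: bool
    invalid_reason: InvalidReason
    bedtime_h: float | None = None
    wakeup_h: float | None = None
    sleep_efficiency: float | None = None
    n_naps: int | None = None
    imputed_fraction: float = 0.0


@dataclass(frozen=True)
class SleepMeasureVector:
    participant_id: str
    bedtime: float
    wakeup_time: float
    sleep_duration: float
    waso: float
    sleep_efficiency: float
    n_awakenings: float
    longest_sleep_bout: float
    n_naps: float
    bedtime_variability: float
    sleep_duration_variability: float
    n_valid_days: int


MEASURE_NAMES = [
    "bedtime",
    "wakeup_time",
    "sleep_duration",
    "waso",
    "sleep_efficiency",
    "n_awakenings",
    "longest_sleep_bout",
    "n_naps",
    "bedtime_variability",
    "sleep_duration_variability",
]


# ---------------------------------------------------------------------------
# time helpers


def _minutes(dt: datetime, origin: datetime) -> float:
    return (dt - origin).total_seconds() / 60.0


def runs_in_minutes(bouts: Sequence[Bout], origin: datetime) -> list[Run]:
    return [
        (_minutes(s, origin), _minutes(e, origin), st is State.SLEEP)
        for s, e, st in state_runs(bouts)
    ]


def clip_runs(runs: Iterable[Run], lo: float, hi: float) -> list[Run]:
    out = []
    for s, e, sl in runs:
        cs, ce = max(s, lo), min(e, hi)
        if cs < ce:
            out.append((cs, ce, sl))
    return out


# ---------------------------------------------------------------------------
# day segmentation


def segment_days(rec: Recording) -> list[tuple[DayWindow, list[Bout]]]:
    """Cut a recording into consecutive 3 PM -> 3 PM windows.

    Windows start at the first 15:00 at or after ``recording_start`` and are
    emitted while they overlap the recording; a window whose 24 hours are not
    fully covered is marked incomplete.  Bouts straddling a boundary are
    split at the boundary, each fragment keeping its state and imputed flag.
    """
    start = rec.recording_start
    first = datetime.combine(start.date(), time(DAY_START_HOUR))
    if first < start:
        first += timedelta(days=1)

    windows: list[tuple[DayWindow, list[Bout]]] = []
    idx = 0
    ws = first
    if rec.recording_end <= first:
        # recording ends before the first 15:00: one incomplete pre-window
        prev = first - timedelta(days=1)
        clipped = _clip_bouts(rec.bouts, prev, first)
        if clipped:
            windows.append((DayWindow(0, prev, first, complete=False), clipped))
        return windows
    while ws < rec.recording_end:
        we = ws + timedelta(days=1)
        complete = ws >= rec.recording_start and we <= rec.recording_end
        clipped = _clip_bouts(rec.bouts, ws, we)
        windows.append((DayWindow(idx, ws, we, complete=complete), clipped))
        idx += 1
        ws = we
    return windows


def _clip_bouts(bouts: Sequence[Bout], lo: datetime, hi: datetime) -> list[Bout]:
    out = []
    for b in bouts:
        s, e = max(b.start, lo), min(b.end, hi)
        if s < e:
            out.append(Bout(s, e, b.state, b.imputed, b.p_sleep))
    return out


# ---------------------------------------------------------------------------
# primary sleep period


def _anchor_chains(runs: Sequence[Run],
                   anchor_minutes: float = ANCHOR_MINUTES,
                   gap_minutes: float = GAP_MINUTES) -> list[tuple[float, float]]:
    """Maximal chains of anchor sleep runs, as (onset, offset) spans."""
    anchors = [(s, e) for s, e, sl in runs if sl and e - s >= anchor_minutes]
    if not anchors:
        return []
    chains: list[tuple[float, float]] = []
    chain_start, chain_end = anchors[0]
    for s, e in anchors[1:]:
        if s - chain_end <= gap_minutes:
            chain_end = e
        else:
            chains.append((chain_start, chain_end))
            chain_start, chain_end = s, e
    chains.append((chain_start, chain_end))
    return chains


def _psp_measures(runs: Sequence[Run], onset: float, offset: float) -> PrimarySleepPeriod:
    inside = clip_runs(runs, onset, offset)
    sleep = sum(e - s for s, e, sl in inside if sl)
    wake_runs = [(s, e) for s, e, sl in inside if not sl]
    waso = sum(e - s for s, e in wake_runs)
    longest = max((e - s for s, e, sl in inside if sl), default=0.0)
    return PrimarySleepPeriod(
        onset_min=onset,
        offset_min=offset,
        sleep_minutes=sleep,
        waso_minutes=waso,
        n_awakenings=len(wake_runs),
        longest_sleep_bout_minutes=longest,
    )


def detect_primary_sleep_period(
    runs: Sequence[Run],
    anchor_minutes: float = ANCHOR_MINUTES,
    gap_minutes: float = GAP_MINUTES,
) -> PrimarySleepPeriod | None:
    """Detect the primary sleep period among same-state runs.

    Returns ``None`` when no sleep run reaches ``anchor_minutes``.  The PSP
    span runs from the first to the last anchor of the chain with the
    longest span; ties break to the earliest onset.  Measures inside the PSP
    count all sleep (anchors and shorter bouts alike), all wake as WASO,
    maximal wake runs as awakenings, and the longest maximal sleep run.
    """
    chains = _anchor_chains(runs, anchor_minutes, gap_minutes)
    if not chains:
        return None
    onset, offset = max(chains, key=lambda c: (c[1] - c[0], -c[0]))
    return _psp_measures(runs, onset, offset)


def count_naps(runs: Sequence[Run], psp: PrimarySleepPeriod,
               nap_minutes: float = NAP_MINUTES) -> int:
    """Count maximal sleep runs wholly outside the PSP lasting strictly more than 30 min."""
    return sum(
        1
        for s, e, sl in runs
        if sl and (e <= psp.onset_min or s >= psp.offset_min) and e - s > nap_minutes
    )


# ---------------------------------------------------------------------------
# day classification


def classify_day(
    day: DayWindow,
    rec: Recording,
    anchor_minutes: float = ANCHOR_MINUTES,
    gap_minutes: float = GAP_MINUTES,
    imputed_max_fraction: float = IMPUTED_MAX_FRACTION,
) -> DaySummary:
    """Classify one day as valid/invalid and compute its per-day measures.

    The PSP is detected on the day's bouts extended by a 6-hour margin either
    side, so that a sleep period straddling a 3 PM boundary can still be seen
    to cross it; among the detected chains, the day's PSP is the
    longest-span chain overlapping the window.  Invalid-reason precedence is
    NO_QUALIFYING_SLEEP > PSP_CROSSES_BOUNDARY > IMPUTED_GT_10PCT, with
    partially covered windows invalid even when the three rules pass.
    """
    origin = day.reference_midnight
    ws = _minutes(day.window_start, origin)
    we = _minutes(day.window_end, origin)
    margin = BOUNDARY_MARGIN_H * 60.0

    all_runs = runs_in_minutes(rec.bouts, origin)
    context = clip_runs(all_runs, ws - margin, we + margin)
    day_runs = clip_runs(all_runs, ws, we)

    imputed_min = sum(
        max(0.0, min(_minutes(b.end, origin), we) - max(_minutes(b.start, origin), ws))
        for b in rec.bouts
        if b.imputed
    )
    imputed_fraction = imputed_min / 1440.0

    # qualifying sleep: any sleep run intersecting the window with full length >= 30 min
    qualifying = any(
        sl and e - s >= anchor_minutes and e > ws and s < we for s, e, sl in context
    )
    if not qualifying:
        return DaySummary(day, None, False, InvalidReason.NO_QUALIFYING_SLEEP,
                          imputed_fraction=imputed_fraction)

    chains = _anchor_chains(context, anchor_minutes, gap_minutes)
    overlapping = [(on, off) for on, off in chains if off > ws and on < we]
    if not overlapping:
        return DaySummary(day, None, False, InvalidReason.NO_QUALIFYING_SLEEP,
                          imputed_fraction=imputed_fraction)
    onset, offset = max(overlapping, key=lambda c: (c[1] - c[0], -c[0]))
    psp = _psp_measures(context, onset, offset)

    if onset < ws or offset > we:
        return DaySummary(day, psp, False, InvalidReason.PSP_CROSSES_BOUNDARY,
                          imputed_fraction=imputed_fraction)
    if imputed_fraction > imputed_max_fraction:
        return DaySummary(day, psp, False, InvalidReason.IMPUTED_GT_10PCT,
                          imputed_fraction=imputed_fraction)
    if not day.complete:
        return DaySummary(day, psp, False, InvalidReason.PARTIAL_COVERAGE,
                          imputed_fraction=imputed_fraction)

    bedtime_h = onset / 60.0
    wakeup_h = offset / 60.0
    efficiency = psp.sleep_minutes / psp.span_minutes
    naps = count_naps(day_runs, psp)
    return DaySummary(
        day, psp, True, InvalidReason.NONE,
        bedtime_h=bedtime_h, wakeup_h=wakeup_h, sleep_efficiency=efficiency,
        n_naps=naps, imputed_fraction=imputed_fraction,
    )


# ---------------------------------------------------------------------------
# participant aggregation


def median_abs_deviation(values: Sequence[float]) -> float:
    """Unscaled MAD: median of absolute deviations from the median."""
    arr = np.asarray(values, dtype=float)
    return float(np.median(np.abs(arr - np.median(arr))))


def mean_abs_deviation(values: Sequence[float]) -> float:
    arr = np.asarray(values, dtype=float)
    return float(np.mean(np.abs(arr - np.median(arr))))


class ParticipantExclusion(enum.Enum):
    NONE = "none"
    LT_MIN_VALID_DAYS = "lt_min_valid_days"
    AFTERNOON_WAKER = "afternoon_waker"


def aggregate_participant(
    participant_id: str,
    days: Sequence[DaySummary],
    min_valid_days: int = MIN_VALID_DAYS,
    afternoon_wakeup_h: float = AFTERNOON_WAKEUP_H,
    variability: str = "median",
) -> tuple[SleepMeasureVector | None, ParticipantExclusion]:
    """Collapse per-day summaries into the participant's 10-measure vector.

    Medians are taken across valid days; the two variability measures use
    the unscaled median absolute deviation by default (``variability="mean"``
    switches to the mean absolute deviation).  Participants with fewer than
    ``min_valid_days`` valid days, or whose median wake-up time is noon or
    later (habitual afternoon wakers, e.g. shift workers), are excluded.
    """
    valid = [d for d in days if d.valid]
    if len(valid) < min_valid_days:
        return None, ParticipantExclusion.LT_MIN_VALID_DAYS

    med = lambda xs: float(np.median(xs))
    dev = median_abs_deviation if variability == "median" else mean_abs_deviation

    wakeup = med([d.wakeup_h for d in valid])
    if wakeup >= afternoon_wakeup_h:
        return None, ParticipantExclusion.AFTERNOON_WAKER

    bedtimes = [d.bedtime_h for d in valid]
    durations_h = [d.psp.sleep_minutes / 60.0 for d in valid]
    vec = SleepMeasureVector(
        participant_id=participant_id,
        bedtime=med(bedtimes),
        wakeup_time=wakeup,
        sleep_duration=med(durations_h),
        waso=med([d.psp.waso_minutes for d in valid]),
        sleep_efficiency=med([d.sleep_efficiency for d in valid]),
        n_awakenings=med([d.psp.n_awakenings for d in valid]),
        longest_sleep_bout=med([d.psp.longest_sleep_bout_minutes / 60.0 for d in valid]),
        n_naps=med([d.n_naps for d in valid]),
        bedtime_variability=dev(bedtimes),
        sleep_duration_variability=dev(durations_h),
        n_valid_days=len(valid),
    )
    return vec, ParticipantExclusion.NONE


# ---------------------------------------------------------------------------
# cohort-level driver


def compute_sleep_measures(
    recordings: Iterable[Recording],
    min_valid_days: int = MIN_VALID_DAYS,
    variability: str = "median",
    anchor_minutes: float = ANCHOR_MINUTES,
    gap_minutes: float = GAP_MINUTES,
    imputed_max_fraction: float = IMPUTED_MAX_FRACTION,
    afternoon_wakeup_h: float = AFTERNOON_WAKEUP_H,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run segmentation, PSP detection and aggregation over a cohort.

    Returns ``(per_day, per_participant, attrition)``: a per-day table with
    validity verdicts and per-day measure values, the per-participant table
    of the 10 measures plus ``n_valid_days``, and an attrition table of
    participant-level exclusion counts.
    """
    day_rows, vec_rows = [], []
    attrition = {r.value: 0 for r in ParticipantExclusion}
    for rec in recordings:
        summaries = [
            classify_day(day, rec, anchor_minutes, gap_minutes, imputed_max_fraction)
            for day, _ in segment_days(rec)
        ]
        for d in summaries:
            day_rows.append(
                {
                    "participant_id": rec.participant_id,
                    "day_index": d.day.day_index,
                    "window_start": d.day.window_start,
                    "valid": d.valid,
                    "invalid_reason": d.invalid_reason.value,
                    "psp_onset_h": None if d.psp is None else d.psp.onset_min / 60.0,
                    "psp_offset_h": None if d.psp is None else d.psp.offset_min / 60.0,
                    "bedtime_h": d.bedtime_h,
                    "wakeup_h": d.wakeup_h,
                    "sleep_duration_h": None if d.psp is None else d.psp.sleep_minutes / 60.0,
                    "waso_min": None if d.psp is None else d.psp.waso_minutes,
                    "sleep_efficiency": d.sleep_efficiency,
                    "n_awakenings": None if d.psp is None else d.psp.n_awakenings,
                    "longest_sleep_bout_h": None
                    if d.psp is None
                    else d.psp.longest_sleep_bout_minutes / 60.0,
                    "n_naps": d.n_naps,
                    "imputed_fraction": d.imputed_fraction,
                }
            )
        vec, reason = aggregate_participant(
            rec.participant_id, summaries, min_valid_days=min_valid_days,
            afternoon_wakeup_h=afternoon_wakeup_h, variability=variability,
        )
        attrition[reason.value] += 1
        if vec is not None:
            vec_rows.append(vars(vec))
    per_day = pd.DataFrame(day_rows)
    per_participant = pd.DataFrame(
        vec_rows, columns=["participant_id", *MEASURE_NAMES, "n_valid_days"]
    )
    attrition_df = pd.DataFrame(
        [{"reason": k, "n": v} for k, v in attrition.items()]
    )
    return per_day, per_participant, attrition_df
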