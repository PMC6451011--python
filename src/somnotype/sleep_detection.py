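"""Sleep-period-time-window (SPT) and sleep-episode detection.

The heuristic works on noon-to-noon day segments so a nocturnal sleep bout is
never split by a day boundary.  Per segment:

1. threshold = ``multiplier`` x the 10th percentile of the day's change
   metric over worn epochs (linear-interpolation percentile), clipped to a
   configurable floor/cap;
2. maximal runs of consecutive epochs with metric < threshold lasting
   >= 30 min become inactivity bouts;
3. bouts strictly less than 60 min apart merge transitively into blocks;
4. the longest block is the SPT window (ties: lower mean metric inside the
   block, then earlier start);
5. within the window, maximal runs of successive raw z-angle changes
   <= 5 degrees lasting >= 5 min are sleep episodes (a change strictly
   larger than 5 degrees breaks a run).

All timing results are reported in hours since the midnight *preceding* the
segment start, so times after the second midnight exceed 24 (2 a.m. = 26).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_features import ChangeMetricSeries, change_metric
from .synthetic_cohort import EpochSeries

__all__ = [
    "DetectionParams",
    "DaySegment",
    "SptWindow",
    "SleepEpisode",
    "NightDetection",
    "NoThresholdError",
    "split_days",
    "day_threshold",
    "inactivity_bouts",
    "merge_bouts",
    "detect_spt_window",
    "detect_sleep_episodes",
    "detect_recording",
    "nights_to_frame",
]


class NoThresholdError(ValueError):
    """Raised when a day segment has too little wear time for a threshold."""


@dataclass(frozen=True)
class DetectionParams:
    threshold_multiplier: float = 15.0
    threshold_floor_deg: float = 0.13
    threshold_cap_deg: float | None = None
    percentile: float = 10.0
    metric_window_minutes: float = 5.0
    bout_min_minutes: float = 30.0
    merge_gap_minutes: float = 60.0
    episode_max_change_deg: float = 5.0
    episode_min_minutes: float = 5.0
    min_wear_hours_for_threshold: float = 1.0


@dataclass
class DaySegment:
    """One noon-to-noon slice of a recording (epoch indices are recording-global)."""

    individual_id: str
    day_index: int
    start_idx: int
    stop_idx: int           # exclusive
    midnight: pd.Timestamp  # the midnight preceding segment start
    complete: bool          # spans a full 24 h of epochs


@dataclass
class SptWindow:
    start: pd.Timestamp
    end: pd.Timestamp
    start_idx: int
    end_idx: int            # exclusive, recording-global
    threshold_used: float
    n_bouts_merged: int


@dataclass
class SleepEpisode:
    start: pd.Timestamp
    end: pd.Timestamp
    start_idx: int
    end_idx: int            # exclusive


@dataclass
class NightDetection:
    individual_id: str
    day_index: int
    midnight: pd.Timestamp
    spt: SptWindow | None
    episodes: list[SleepEpisode] = field(default_factory=list)
    bouts: list[tuple[int, int]] = field(default_factory=list)  # merged-block inputs, global idx
    skip_reason: str | None = None


def split_days(series: EpochSeries) -> list[DaySegment]:
    """Cut a recording into noon-to-noon segments; partial segments are flagged."""
    t = series.timestamps
    per_day = 86400 // series.epoch_s
    # first noon at or before the recording start
    first_noon = t[0].normalize() + pd.Timedelta(hours=12)
    if first_noon > t[0]:
        first_noon -= pd.Timedelta(days=1)
    segments: list[DaySegment] = []
    day = 0
    while True:
        seg_start = first_noon + pd.Timedelta(days=day)
        seg_stop = seg_start + pd.Timedelta(days=1)
        if seg_start >= t[-1] + pd.Timedelta(seconds=series.epoch_s):
            break
        i0 = int(np.searchsorted(t.asi8, seg_start.value, side="left"))
        i1 = int(np.searchsorted(t.asi8, seg_stop.value, side="left"))
        if i1 > i0:
            segments.append(
                DaySegment(
                    individual_id=series.individual_id,
                    day_index=day,
                    start_idx=i0,
                    stop_idx=i1,
                    midnight=seg_start.normalize(),
                    complete=(i1 - i0) == per_day,
                )
            )
        day += 1
        if seg_stop > t[-1]:
            break
    return segments


def day_threshold(
    metric: np.ndarray,
    wear: np.ndarray,
    epoch_s: int,
    params: DetectionParams = DetectionParams(),
) -> float:
    """Movement/non-movement threshold for one day segment.

    ``multiplier x percentile`` of the worn-epoch metric values, linear
    interpolation between order statistics, clipped to [floor, cap].
    """
    metric = np.asarray(metric, dtype=float)
    wear = np.asarray(wear, dtype=bool)
    worn = metric[wear]
    if worn.size * epoch_s < params.min_wear_hours_for_threshold * 3600.0:
        raise NoThresholdError("insufficient wear time to estimate a day threshold")
    thr = params.threshold_multiplier * float(np.percentile(worn, params.percentile))
    thr = max(thr, params.threshold_floor_deg)
    if params.threshold_cap_deg is not None:
        thr = min(thr, params.threshold_cap_deg)
    return thr


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
    starts = np.nonzero(padded == 1)[0]
    stops = np.nonzero(padded == -1)[0]
    return list(zip(starts.tolist(), stops.tolist()))


def inactivity_bouts(
    metric: np.ndarray,
    threshold: float,
    epoch_s: int,
    wear: np.ndarray | None = None,
    min_minutes: float = 30.0,
) -> list[tuple[int, int]]:
    """Maximal sub-threshold runs lasting >= min_minutes (non-wear breaks runs)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    below = np.asarray(metric, dtype=float) < threshold
    if wear is not None:
        below &= np.asarray(wear, dtype=bool)
    min_epochs = int(round(min_minutes * 60.0 / epoch_s))
    return [(a, b) for a, b in _runs(below) if (b - a) >= min_epochs]


def merge_bouts(
    bouts: list[tuple[int, int]], epoch_s: int, gap_minutes: float = 60.0
) -> list[tuple[int, int]]:
    """Transitively merge bouts whose gaps are strictly < gap_minutes."""
    if not bouts:
        return []
    bouts = sorted(bouts)
    gap_epochs = gap_minutes * 60.0 / epoch_s
    merged = [list(bouts[0])]
    for a, b in bouts[1:]:
        if a < merged[-1][0]:
            raise ValueError("bouts must be disjoint and sorted")
        if (a - merged[-1][1]) < gap_epochs:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(m) for m in merged]


def detect_spt_window(
    segment: DaySegment,
    metric: ChangeMetricSeries,
    series: EpochSeries,
    params: DetectionParams = DetectionParams(),
) -> tuple[SptWindow | None, list[tuple[int, int]]]:
    """Longest merged inactivity block of the segment, or ``None``.

    Returns (window, merged_blocks) with recording-global epoch indices.
    Ties on block length break on lower mean metric, then earlier start.
    """
    sl = slice(segment.start_idx, segment.stop_idx)
    m = metric.value[sl]
    w = series.wear[sl]
    thr = day_threshold(m, w, series.epoch_s, params)
    bouts = inactivity_bouts(m, thr, series.epoch_s, wear=w, min_minutes=params.bout_min_minutes)
    blocks = merge_bouts(bouts, series.epoch_s, gap_minutes=params.merge_gap_minutes)
    blocks_global = [(a + segment.start_idx, b + segment.start_idx) for a, b in blocks]
    if not blocks:
        return None, blocks_global
    n_in_block: dict[tuple[int, int], int] = {}
    for block in blocks:
        n_in_block[block] = sum(1 for a, b in bouts if block[0] <= a and b <= block[1])
    best = min(blocks, key=lambda ab: (-(ab[1] - ab[0]), float(np.mean(m[ab[0] : ab[1]])), ab[0]))
    a, b = best[0] + segment.start_idx, best[1] + segment.start_idx
    window = SptWindow(
        start=series.timestamps[a],
        end=series.timestamps[b - 1] + pd.Timedelta(seconds=series.epoch_s),
        start_idx=a,
        end_idx=b,
        threshold_used=thr,
        n_bouts_merged=n_in_block[best],
    )
    return window, blocks_global


def detect_sleep_episodes(
    series: EpochSeries,
    window: SptWindow,
    params: DetectionParams = DetectionParams(),
) -> list[SleepEpisode]:
    """Sleep episodes inside an SPT window from raw epoch z-angles.

    A run of successive-epoch changes all <= 5 degrees spanning epochs
    [i, j] is an episode when (j - i + 1) epochs last >= 5 min; a change
    strictly > 5 degrees breaks the run.
    """
    z = series.z_angle[window.start_idx : window.end_idx]
    if z.size == 0:
        return []
    min_epochs = int(round(params.episode_min_minutes * 60.0 / series.epoch_s))
    ok = np.abs(np.diff(z)) <= params.episode_max_change_deg
    episodes: list[SleepEpisode] = []
    for a, b in _runs(ok):
        i0, i1 = a, b + 1  # diffs [a, b) cover epochs [a, b]
        if (i1 - i0) < min_epochs:
            continue
        g0, g1 = i0 + window.start_idx, i1 + window.start_idx
        episodes.append(
            SleepEpisode(
                start=series.timestamps[g0],
                end=series.timestamps[g1 - 1] + pd.Timedelta(seconds=series.epoch_s),
                start_idx=g0,
                end_idx=g1,
            )
        )
    return episodes


def detect_recording(
    series: EpochSeries, params: DetectionParams = DetectionParams()
) -> list[NightDetection]:
    """Run the full per-day pipeline over one recording."""
    metric = change_metric(series, window_minutes=params.metric_window_minutes)
    nights: list[NightDetection] = []
    for segment in split_days(series):
        night = NightDetection(
            individual_id=series.individual_id,
            day_index=segment.day_index,
            midnight=segment.midnight,
            spt=None,
        )
        try:
            window, blocks = detect_spt_window(segment, metric, series, params)
        except NoThresholdError as exc:
            night.skip_reason = str(exc)
            nights.append(night)
            continue
        night.bouts = blocks
        if window is None:
            night.skip_reason = "no inactivity block"
        else:
            night.spt = window
            night.episodes = detect_sleep_episodes(series, window, params)
        nights.append(night)
    return nights


def nights_to_frame(nights: list[NightDetection]) -> pd.DataFrame:
    """One row per individual-night, for the ``detect`` CLI output."""
    rows = []
    for night in nights:
        row: dict = {
            "individual_id": night.individual_id,
            "day_index": night.day_index,
            "spt_start": night.spt.start.isoformat() if night.spt else "",
            "spt_end": night.spt.end.isoformat() if night.spt else "",
            "n_episodes": len(night.episodes),
            "episodes": ";".join(
                f"{e.start.isoformat()}/{e.end.isoformat()}" for e in night.episodes
            ),
            "threshold_used": night.spt.threshold_used if night.spt else np.nan,
            "skip_reason": night.skip_reason or "",
        }
        rows.append(row)
    return pd.DataFrame(rows)
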