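"""Derivation of the eight sleep measures, the exclusion cascade, and
phenotype-preparation utilities (rank-based inverse-normal transform and OLS
residualisation).

The eight measures per individual:

* mean nocturnal sleep duration (h) and its night-to-night SD (maximum-wear
  individuals only),
* sleep efficiency (sleep duration / SPT-window length),
* number of nocturnal sleep episodes,
* sleep midpoint, L5 midpoint and M10 midpoint (hours since the previous
  midnight; 2 a.m. = 26),
* diurnal inactivity (hours of inactivity bouts outside the SPT window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .sleep_detection import (
    DetectionParams,
    NightDetection,
    SptWindow,
    SleepEpisode,
    detect_recording,
    split_days,
)
from .synthetic_cohort import EpochSeries

__all__ = [
    "NightRecord",
    "DayActivityRecord",
    "PhenotypeRecord",
    "night_summary",
    "l5_m10",
    "diurnal_inactivity",
    "aggregate_individual",
    "derive_individual",
    "derive_cohort",
    "phenotype_frame",
    "apply_exclusions",
    "inverse_normal",
    "residualize",
]

PHENOTYPE_COLUMNS = [
    "mean_sleep_duration",
    "sd_sleep_duration",
    "mean_efficiency",
    "mean_n_episodes",
    "mean_midpoint",
    "mean_l5",
    "mean_m10",
    "mean_diurnal_inactivity",
]


@dataclass
class NightRecord:
    individual_id: str
    night_index: int
    sleep_duration: float   # hours, sum of episodes
    spt_length: float       # hours
    efficiency: float       # in (0, 1]
    n_episodes: int
    midpoint: float         # hours since previous midnight
    valid: bool


@dataclass
class DayActivityRecord:
    individual_id: str
    day_index: int
    l5_midpoint: float | None
    m10_midpoint: float | None
    diurnal_inactivity: float  # hours
    valid_wear_hours: float


@dataclass
class PhenotypeRecord:
    individual_id: str
    mean_sleep_duration: float = np.nan
    sd_sleep_duration: float = np.nan
    mean_efficiency: float = np.nan
    mean_n_episodes: float = np.nan
    mean_midpoint: float = np.nan
    mean_l5: float = np.nan
    mean_m10: float = np.nan
    mean_diurnal_inactivity: float = np.nan
    n_nights_used: int = 0
    n_days_used: int = 0
    n_days_worn: int = 0
    excluded: bool = False
    exclusion_reasons: list[str] = field(default_factory=list)


def _hours(ts: pd.Timestamp, midnight: pd.Timestamp) -> float:
    return (ts - midnight).total_seconds() / 3600.0


def night_summary(
    window: SptWindow, episodes: list[SleepEpisode], midnight: pd.Timestamp,
    individual_id: str = "", night_index: int = 0,
) -> NightRecord:
    """Summarise one night: duration = sum of episodes, efficiency =
    duration / SPT length, midpoint = centre of [first episode start, last
    episode end] in hours since the previous midnight."""
    spt_length = (window.end - window.start).total_seconds() / 3600.0
    if not episodes:
        return NightRecord(individual_id, night_index, 0.0, spt_length, np.nan, 0, np.nan, valid=False)
    duration = sum((e.end - e.start).total_seconds() for e in episodes) / 3600.0
    midpoint = 0.5 * (_hours(episodes[0].start, midnight) + _hours(episodes[-1].end, midnight))
    return NightRecord(
        individual_id=individual_id,
        night_index=night_index,
        sleep_duration=duration,
        spt_length=spt_length,
        efficiency=duration / spt_length,
        n_episodes=len(episodes),
        midpoint=midpoint,
        valid=True,
    )


def l5_m10(
    magnitude: np.ndarray,
    wear: np.ndarray,
    epoch_s: int,
    start_hours_since_midnight: float = 12.0,
    min_wear_hours: float = 16.0,
) -> tuple[float | None, float | None]:
    """Midpoints of the least-active 5 h and most-active 10 h of a day
    segment, in hours since the previous midnight.

    Windows slide at epoch resolution and must fit entirely inside the
    segment; ties select the earliest window.  Returns (None, None) when the
    segment has fewer than ``min_wear_hours`` of wear.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    wear = np.asarray(wear, dtype=bool)
    if wear.sum() * epoch_s < min_wear_hours * 3600.0:
        return None, None

    def _window_midpoint(hours: float, minimise: bool) -> float | None:
        w = int(round(hours * 3600.0 / epoch_s))
        if w > magnitude.size:
            return None
        c = np.concatenate([[0.0], np.cumsum(magnitude)])
        means = (c[w:] - c[:-w]) / w
        i = int(np.argmin(means) if minimise else np.argmax(means))
        centre_s = (i + w / 2.0) * epoch_s
        return start_hours_since_midnight + centre_s / 3600.0

    return _window_midpoint(5.0, minimise=True), _window_midpoint(10.0, minimise=False)


def diurnal_inactivity(
    bouts: list[tuple[int, int]], window: SptWindow | None, epoch_s: int
) -> float:
    """Hours of inactivity bouts falling outside the SPT window (bouts
    straddling a boundary contribute only their outside portion)."""
    total_epochs = 0
    for a, b in bouts:
        if window is None:
            total_epochs += b - a
            continue
        overlap = max(0, min(b, window.end_idx) - max(a, window.start_idx))
        total_epochs += (b - a) - overlap
    return total_epochs * epoch_s / 3600.0


def aggregate_individual(
    nights: list[NightRecord],
    days: list[DayActivityRecord],
    n_days_worn: int,
    max_days: int = 7,
) -> PhenotypeRecord | None:
    """Per-phenotype means over valid nights/days.

    The night-to-night sleep-duration SD (sample SD, n-1 denominator) is
    reported only for individuals who wore the device the maximum number of
    days.  Returns ``None`` when no valid night exists.
    """
    valid_nights = [n for n in nights if n.valid]
    if not valid_nights:
        return None
    ind = valid_nights[0].individual_id
    durations = np.array([n.sleep_duration for n in valid_nights])
    rec = PhenotypeRecord(individual_id=ind)
    rec.mean_sleep_duration = float(np.mean(durations))
    if n_days_worn == max_days and len(durations) >= 2:
        rec.sd_sleep_duration = float(np.std(durations, ddof=1))
    rec.mean_efficiency = float(np.mean([n.efficiency for n in valid_nights]))
    rec.mean_n_episodes = float(np.mean([n.n_episodes for n in valid_nights]))
    rec.mean_midpoint = float(np.mean([n.midpoint for n in valid_nights]))
    l5s = [d.l5_midpoint for d in days if d.l5_midpoint is not None]
    m10s = [d.m10_midpoint for d in days if d.m10_midpoint is not None]
    rec.mean_l5 = float(np.mean(l5s)) if l5s else np.nan
    rec.mean_m10 = float(np.mean(m10s)) if m10s else np.nan
    rec.mean_diurnal_inactivity = float(np.mean([d.diurnal_inactivity for d in days])) if days else np.nan
    rec.n_nights_used = len(valid_nights)
    rec.n_days_used = len(l5s)
    rec.n_days_worn = n_days_worn
    return rec


def derive_individual(
    series: EpochSeries,
    params: DetectionParams = DetectionParams(),
    max_days: int = 7,
) -> tuple[PhenotypeRecord | None, list[NightRecord], list[DayActivityRecord]]:
    """Full chain for one recording: detection -> per-night and per-day
    records -> aggregated phenotypes."""
    nights_det = detect_recording(series, params)
    segments = {s.day_index: s for s in split_days(series)}
    night_records: list[NightRecord] = []
    day_records: list[DayActivityRecord] = []
    for night in nights_det:
        seg = segments[night.day_index]
        if night.spt is not None:
            night_records.append(
                night_summary(
                    night.spt, night.episodes, night.midnight,
                    individual_id=series.individual_id, night_index=night.day_index,
                )
            )
        sl = slice(seg.start_idx, seg.stop_idx)
        wear = series.wear[sl]
        l5, m10 = (None, None)
        if seg.complete:
            l5, m10 = l5_m10(series.magnitude[sl], wear, series.epoch_s)
        day_records.append(
            DayActivityRecord(
                individual_id=series.individual_id,
                day_index=night.day_index,
                l5_midpoint=l5,
                m10_midpoint=m10,
                diurnal_inactivity=diurnal_inactivity(night.bouts, night.spt, series.epoch_s),
                valid_wear_hours=float(wear.sum()) * series.epoch_s / 3600.0,
            )
        )
    n_days_worn = len([s for s in segments.values() if s.complete])
    record = aggregate_individual(night_records, day_records, n_days_worn, max_days=max_days)
    return record, night_records, day_records


def derive_cohort(
    recordings: list[EpochSeries],
    params: DetectionParams = DetectionParams(),
    max_days: int = 7,
) -> pd.DataFrame:
    """Phenotype table with one row per individual (individuals with no
    valid night are dropped)."""
    records = []
    for series in recordings:
        rec, _, _ = derive_individual(series, params, max_days=max_days)
        if rec is not None:
            records.append(rec)
    return phenotype_frame(records)


def phenotype_frame(records: list[PhenotypeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"individual_id": r.individual_id}
        row.update({c: getattr(r, c) for c in PHENOTYPE_COLUMNS})
        row.update(
            {
                "n_nights_used": r.n_nights_used,
                "n_days_used": r.n_days_used,
                "n_days_worn": r.n_days_worn,
                "excluded": r.excluded,
                "exclusion_reasons": ";".join(r.exclusion_reasons),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def apply_exclusions(
    phenotypes: pd.DataFrame,
    qc_flags: pd.Series | None = None,
    qc_counters: pd.DataFrame | None = None,
    min_duration: float = 3.0,
    max_duration: float = 12.0,
    min_episodes: float = 5.0,
    max_episodes: float = 30.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sequential exclusion cascade; returns (retained, exclusion log).

    1. ``device_flag``  — explicit device-QC booleans, indexed by individual;
    2. ``qc_iqr:<col>`` — per-counter rule: value strictly greater than
       Q3 + 1.5 x IQR (type-7 linear-interpolation quartiles), computed on
       the survivors of rule 1;
    3. ``duration_bounds`` — mean sleep duration strictly < 3 h or > 12 h;
    4. ``episode_bounds``  — mean episode count <= 5 or >= 30 (closed bounds).

    Rules 3-4 apply to SPT-based phenotypes; L5/M10-only analyses may
    re-admit those individuals via the log.  The returned ``retained`` frame
    contains individuals hit by no rule, with idempotent re-application.
    """
    if phenotypes.empty:
        raise ValueError("phenotype table is empty")
    df = phenotypes.set_index("individual_id", drop=False)
    log: list[dict] = []

    def exclude(ind: str, rule: str, detail: str) -> None:
        log.append({"individual_id": ind, "rule": rule, "detail": detail})

    flagged: set[str] = set()
    if qc_flags is not None:
        for ind, bad in qc_flags.items():
            if bool(bad) and ind in df.index:
                flagged.add(ind)
                exclude(ind, "device_flag", "device QC flag set")

    if qc_counters is not None:
        survivors = qc_counters.loc[[i for i in qc_counters.index if i not in flagged]]
        for col in qc_counters.columns:
            vals = survivors[col].to_numpy(float)
            q1, q3 = np.percentile(vals, [25, 75])  # type-7 linear interpolation
            cutoff = q3 + 1.5 * (q3 - q1)
            for ind in survivors.index[survivors[col] > cutoff]:
                if ind in df.index:
                    flagged.add(ind)
                    exclude(ind, f"qc_iqr:{col}", f"{col}={survivors.at[ind, col]} > {cutoff:g}")

    spt_excluded: set[str] = set()
    for ind, row in df.iterrows():
        if ind in flagged:
            continue
        dur = row["mean_sleep_duration"]
        if dur < min_duration or dur > max_duration:
            spt_excluded.add(ind)
            exclude(ind, "duration_bounds", f"mean sleep duration {dur:.2f} h")
        eps = row["mean_n_episodes"]
        if eps <= min_episodes or eps >= max_episodes:
            spt_excluded.add(ind)
            exclude(ind, "episode_bounds", f"mean episodes {eps:.2f}")

    dropped = flagged | spt_excluded
    retained = phenotypes[~phenotypes["individual_id"].isin(dropped)].copy()
    log_df = pd.DataFrame(log, columns=["individual_id", "rule", "detail"])
    return retained, log_df


def inverse_normal(values) -> np.ndarray:
    """Rank-based inverse-normal (Blom) transform:
    ``ndtri((rank - 3/8) / (n + 1/4))`` with mean ranks for ties."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("inverse_normal needs at least two values")
    if np.all(values == values[0]):
        raise ValueError("inverse_normal undefined for a constant vector")
    ranks = rankdata(values, method="average")
    return ndtri((ranks - 0.375) / (values.size + 0.25))


def residualize(
    frame: pd.DataFrame, phenotype: str, covariates: list[str]
) -> np.ndarray:
    """OLS residuals of ``phenotype`` on an intercept plus ``covariates``
    (categorical covariates are dummy-coded)."""
    y = frame[phenotype].to_numpy(float)
    X = pd.get_dummies(frame[covariates], drop_first=True, dtype=float)
    X.insert(0, "_intercept", 1.0)
    Xm = X.to_numpy(float)
    beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
    return y - Xm @ beta
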