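"""Synthetic wrist-accelerometer cohort generator with known sleep structure.

Produces epoch-level recordings (z-angle, ENMO-style activity magnitude, wear
mask) together with a ground-truth diary of sleep-period windows, sleep
episodes, naps and non-wear gaps, so that the whole detection/phenotyping
chain can be validated without any real data.

Signal model
------------
* Recordings start at local noon and span ``n_days`` x 24 h at ``epoch_s``
  resolution, so each noon-to-noon day segment contains exactly one night.
* During a sleep episode the z-angle is a held orientation (drawn uniformly
  in [-60, 60] degrees) plus Gaussian micro-noise; wake-after-sleep-onset
  (WASO) bursts and episode boundaries re-draw the held angle with a minimum
  displacement of ``posture_shift_min_deg``.
* Awake epochs re-draw the angle every epoch, giving large successive
  changes that the change-metric threshold separates from sleep.
* Activity magnitude follows a 24-h cosine whose trough is placed so the
  least-active 5-h window is centred on ``l5_phase_hours`` (hours since the
  previous midnight, may exceed 24), plus non-negative noise.

All randomness flows through a single :class:`numpy.random.Generator`; the
same (config, seed) always yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "EpochSeries",
    "NightTruth",
    "TruthDiary",
    "generate_recording",
    "generate_cohort",
    "epochs_to_raw_samples",
    "write_epochs_csv",
    "write_truth_tsv",
    "truth_to_frame",
]

_EPOCH_START = pd.Timestamp("2020-01-06 12:00:00")  # arbitrary Monday noon


class ConfigurationError(ValueError):
    """Raised when a GeneratorConfig fails validation."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Calibration of the synthetic cohort.

    Distributional defaults target the cohort summary values used throughout
    the test-suite: mean nightly sleep duration 7.30 h (between-individual SD
    0.86 h, night-to-night SD 0.93 h) and least-active-5-h midpoint 27.32 h
    from the previous midnight.
    """

    n_individuals: int = 1
    n_days: int = 7
    epoch_s: int = 5
    sleep_onset_mean: float = 23.5      # clock hours from midnight
    sleep_onset_sd: float = 0.75
    true_duration_mean: float = 7.3     # hours of actual sleep per night
    true_duration_sd_between: float = 0.86
    true_duration_sd_within: float = 0.93
    waso_bouts_per_night: float = 8.0   # Poisson rate of movement bursts
    waso_bout_minutes: float = 2.0      # mean burst length (exponential)
    micro_movement_sd: float = 1.0      # degrees, within-episode z-angle noise
    posture_shift_min_deg: float = 20.0
    nap_probability: float = 0.0        # per day
    nonwear_probability: float = 0.0    # per day
    activity_day_amplitude: float = 0.10  # g, peak-to-trough of diurnal curve
    magnitude_noise_sd: float = 0.01    # g
    l5_phase_hours: float = 27.32       # target L5 midpoint, hours since prev midnight
    seed: int = 0

    def validate(self) -> None:
        if not 1 <= self.n_days <= 7:
            raise ConfigurationError("n_days must be in [1, 7]")
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be >= 1")
        if self.epoch_s <= 0 or 60 % self.epoch_s != 0:
            raise ConfigurationError("epoch_s must be a positive divisor of 60 s")
        if self.posture_shift_min_deg <= 5.0:
            raise ConfigurationError("posture_shift_min_deg must exceed 5 degrees")
        # mean |step| for N(0, sd) differences is 2*sd/sqrt(pi); keep the
        # expected within-episode change comfortably below the 5-degree
        # episode-break rule.
        if 2.0 * self.micro_movement_sd / math.sqrt(math.pi) >= 5.0:
            raise ConfigurationError(
                "micro_movement_sd too large: expected within-sleep change must stay below 5 degrees"
            )
        for name in ("sleep_onset_sd", "true_duration_sd_between", "true_duration_sd_within",
                     "waso_bouts_per_night", "waso_bout_minutes", "micro_movement_sd",
                     "activity_day_amplitude", "magnitude_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("nap_probability", "nonwear_probability"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be a probability in [0, 1]")
        if not 3.0 < self.true_duration_mean < 12.0:
            raise ConfigurationError("true_duration_mean must lie in (3, 12) hours")


@dataclass
class EpochSeries:
    """Epoch-level recording for one individual."""

    individual_id: str
    timestamps: pd.DatetimeIndex
    z_angle: np.ndarray      # degrees, in [-90, 90]
    magnitude: np.ndarray    # g, >= 0 (ENMO-style)
    wear: np.ndarray         # bool
    epoch_s: int

    def __post_init__(self) -> None:
        n = len(self.timestamps)
        if not (len(self.z_angle) == len(self.magnitude) == len(self.wear) == n):
            raise ValueError("EpochSeries arrays must share one length")

    def validate(self) -> None:
        dt = np.diff(self.timestamps.asi8)
        if len(dt) and not np.all(dt == self.epoch_s * 1_000_000_000):
            raise ValueError("timestamps must be strictly increasing with uniform epoch spacing")
        if np.any(self.z_angle < -90.0) or np.any(self.z_angle > 90.0):
            raise ValueError("z_angle out of [-90, 90]")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be non-negative")


@dataclass
class NightTruth:
    night_index: int
    spt_start: pd.Timestamp
    spt_end: pd.Timestamp
    episodes: list[tuple[pd.Timestamp, pd.Timestamp]]
    naps: list[tuple[pd.Timestamp, pd.Timestamp]]
    nonwear: list[tuple[pd.Timestamp, pd.Timestamp]]
    l5_midpoint: float   # hours since previous midnight
    m10_midpoint: float

    @property
    def sleep_duration_hours(self) -> float:
        return sum((e - s).total_seconds() for s, e in self.episodes) / 3600.0


@dataclass
class TruthDiary:
    individual_id: str
    nights: list[NightTruth] = field(default_factory=list)


def _draw_held_angle(rng: np.random.Generator, previous: float | None, min_shift: float) -> float:
    """Uniform held orientation in [-60, 60], at least min_shift away from previous."""
    for _ in range(1000):
        cand = rng.uniform(-60.0, 60.0)
        if previous is None or abs(cand - previous) >= min_shift:
            return cand
    raise RuntimeError("could not draw a held angle with the requested displacement")


def _fill_movement(rng: np.random.Generator, z: np.ndarray, start: int, stop: int) -> None:
    """Awake movement: re-draw the angle each epoch, forcing successive
    changes > 5 degrees so the raw episode rule always breaks here."""
    prev = z[start - 1] if start > 0 else rng.uniform(-60.0, 60.0)
    for i in range(start, stop):
        for _ in range(100):
            cand = rng.uniform(-60.0, 60.0)
            if abs(cand - prev) > 6.0:
                break
        z[i] = cand
        prev = cand


def _plan_night(
    rng: np.random.Generator, cfg: GeneratorConfig, mu_duration: float
) -> tuple[float, list[float], list[float]]:
    """Return (onset hours since day midnight, episode durations h, burst durations h).

    Episode and burst pieces alternate: ep0, burst0, ep1, ..., ep_k.  All
    pieces are at least 6 minutes (episodes) so the >=5-min detector rule
    never silently drops a true episode.
    """
    onset = rng.normal(cfg.sleep_onset_mean, cfg.sleep_onset_sd)
    onset = float(np.clip(onset, 20.0, 26.0))
    duration = rng.normal(mu_duration, cfg.true_duration_sd_within)
    duration = float(np.clip(duration, 3.5, 11.5))
    for _ in range(200):
        k = rng.poisson(cfg.waso_bouts_per_night)
        if k == 0:
            episodes = [duration]
            bursts: list[float] = []
            break
        cuts = np.sort(rng.uniform(0.05 * duration, 0.95 * duration, size=k))
        pieces = np.diff(np.concatenate([[0.0], cuts, [duration]]))
        if np.min(pieces) >= 0.1:  # every true episode >= 6 min
            episodes = [float(p) for p in pieces]
            # bursts are capped below half the 5-min metric window so a WASO
            # movement burst can never flip the rolling median and split the
            # night's inactivity run
            bursts = [
                float(np.clip(rng.exponential(cfg.waso_bout_minutes / 60.0), 1.0 / 60.0, 2.0 / 60.0))
                for _ in range(k)
            ]
            break
    else:  # pragma: no cover - rejection loop essentially always succeeds
        episodes, bursts = [duration], []
    return onset, episodes, bursts


def generate_recording(
    config: GeneratorConfig, individual_id: str, seed: int | None = None
) -> tuple[EpochSeries, TruthDiary]:
    """Generate one individual's recording plus its ground-truth diary.

    ``seed`` overrides ``config.seed``; identical (config, seed) pairs return
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    epoch_s = config.epoch_s
    per_day = 86400 // epoch_s
    n = config.n_days * per_day
    timestamps = _EPOCH_START + pd.to_timedelta(np.arange(n) * epoch_s, unit="s")
    timestamps = pd.DatetimeIndex(timestamps)

    # start fully awake (fresh angle every epoch); still periods overwritten below
    z = rng.uniform(-60.0, 60.0, size=n)
    wear = np.ones(n, dtype=bool)

    # diurnal activity magnitude: cosine trough centred on the L5 target
    hours = 12.0 + np.arange(n) * (epoch_s / 3600.0)  # hours since midnight of day 0
    trough = config.l5_phase_hours % 24.0
    curve = 0.5 * config.activity_day_amplitude * (1.0 - np.cos(2.0 * np.pi * (hours - trough) / 24.0))
    magnitude = np.maximum(curve + rng.normal(0.0, config.magnitude_noise_sd, size=n), 0.0)

    mu_duration = rng.normal(config.true_duration_mean, config.true_duration_sd_between)
    mu_duration = float(np.clip(mu_duration, 4.0, 11.0))

    diary = TruthDiary(individual_id=individual_id)

    def to_index(hours_from_day0_midnight: float) -> int:
        # recording starts at hour 12 of day 0
        return int(round((hours_from_day0_midnight - 12.0) * 3600.0 / epoch_s))

    for day in range(config.n_days):
        onset_h, episodes_h, bursts_h = _plan_night(rng, config, mu_duration)
        # keep the whole night inside its noon-to-noon segment
        total_h = sum(episodes_h) + sum(bursts_h)
        overflow = (onset_h + total_h) - 35.9
        if overflow > 0:
            onset_h -= overflow
        # absolute hours from day-0 midnight
        cursor = 24.0 * day + onset_h
        spt_start_h = cursor
        episode_ivals: list[tuple[int, int]] = []
        burst_ivals: list[tuple[int, int]] = []
        for j, ep in enumerate(episodes_h):
            i0, i1 = to_index(cursor), to_index(cursor + ep)
            episode_ivals.append((i0, i1))
            cursor += ep
            if j < len(bursts_h):
                b0, b1 = to_index(cursor), to_index(cursor + bursts_h[j])
                burst_ivals.append((b0, max(b1, b0 + 1)))
                cursor += bursts_h[j]
        spt_end_h = cursor

        prev_angle: float | None = None
        for i0, i1 in episode_ivals:
            held = _draw_held_angle(rng, prev_angle, config.posture_shift_min_deg)
            noise = rng.normal(0.0, config.micro_movement_sd, size=i1 - i0) if config.micro_movement_sd > 0 else 0.0
            z[i0:i1] = np.clip(held + noise, -90.0, 90.0)
            prev_angle = held
        for b0, b1 in burst_ivals:
            _fill_movement(rng, z, b0, b1)
        # force clean posture breaks at both SPT boundaries
        first = episode_ivals[0][0]
        last = episode_ivals[-1][1]
        if first > 0 and abs(z[first - 1] - z[first]) <= 6.0:
            z[first - 1] = np.clip(z[first] + math.copysign(rng.uniform(10.0, 40.0), rng.standard_normal()), -90, 90)
        if last < n and abs(z[last] - z[last - 1]) <= 6.0:
            z[last] = np.clip(z[last - 1] + math.copysign(rng.uniform(10.0, 40.0), rng.standard_normal()), -90, 90)

        naps: list[tuple[pd.Timestamp, pd.Timestamp]] = []
        if rng.random() < config.nap_probability:
            nap_start_h = 24.0 * day + rng.uniform(12.5, 16.0)
            nap_len = rng.uniform(0.6, 1.5)
            n0, n1 = to_index(nap_start_h), to_index(nap_start_h + nap_len)
            held = _draw_held_angle(rng, float(z[n0 - 1]) if n0 > 0 else None, config.posture_shift_min_deg)
            noise = rng.normal(0.0, config.micro_movement_sd, size=n1 - n0) if config.micro_movement_sd > 0 else 0.0
            z[n0:n1] = np.clip(held + noise, -90.0, 90.0)
            if n1 < n and abs(z[n1] - z[n1 - 1]) <= 6.0:
                z[n1] = np.clip(z[n1 - 1] + 15.0, -90.0, 90.0)
            naps.append((timestamps[n0], timestamps[n1 - 1] + pd.Timedelta(seconds=epoch_s)))

        nonwear: list[tuple[pd.Timestamp, pd.Timestamp]] = []
        if rng.random() < config.nonwear_probability:
            gap_start_h = 24.0 * (day + 1) + rng.uniform(8.0, 9.5)
            gap_len = rng.uniform(1.0, 3.0)
            g0 = to_index(gap_start_h)
            g1 = min(to_index(gap_start_h + gap_len), n)
            if g0 < n and g1 > g0:
                wear[g0:g1] = False
                magnitude[g0:g1] = 0.0
                z[g0:g1] = z[g0 - 1] if g0 > 0 else 0.0
                nonwear.append((timestamps[g0], timestamps[g1 - 1] + pd.Timedelta(seconds=epoch_s)))

        diary.nights.append(
            NightTruth(
                night_index=day,
                spt_start=timestamps[to_index(spt_start_h)],
                spt_end=timestamps[to_index(spt_end_h) - 1] + pd.Timedelta(seconds=epoch_s),
                episodes=[
                    (timestamps[i0], timestamps[i1 - 1] + pd.Timedelta(seconds=epoch_s))
                    for i0, i1 in episode_ivals
                ],
                naps=naps,
                nonwear=nonwear,
                l5_midpoint=config.l5_phase_hours,
                # most-active 10-h window must fit inside the noon-to-noon
                # segment, so its midpoint is the cosine peak clamped to
                # [17, 31] hours since the previous midnight
                m10_midpoint=float(np.clip((config.l5_phase_hours % 24.0) + 12.0, 17.0, 31.0)),
            )
        )

    series = EpochSeries(
        individual_id=individual_id,
        timestamps=timestamps,
        z_angle=z,
        magnitude=magnitude,
        wear=wear,
        epoch_s=epoch_s,
    )
    return series, diary


def generate_cohort(config: GeneratorConfig) -> tuple[list[EpochSeries], list[TruthDiary]]:
    """Generate ``config.n_individuals`` recordings with per-individual seeds
    derived deterministically from the master seed."""
    config.validate()
    children = np.random.SeedSequence(config.seed).spawn(config.n_individuals)
    width = max(4, len(str(config.n_individuals)))
    recordings: list[EpochSeries] = []
    truths: list[TruthDiary] = []
    for i, child in enumerate(children):
        ind_id = f"S{i + 1:0{width}d}"
        seed = int(child.generate_state(1)[0])
        series, diary = generate_recording(config, ind_id, seed=seed)
        recordings.append(series)
        truths.append(diary)
    return recordings, truths


def epochs_to_raw_samples(
    series: EpochSeries, hz: int = 1, jitter_g: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Expand an epoch series to raw tri-axial samples (for testing the
    raw -> epoch aggregation path).

    Each epoch becomes ``hz * epoch_s`` samples of a unit-gravity vector
    oriented at the epoch z-angle, scaled by (1 + magnitude), plus optional
    Gaussian jitter.
    """
    rng = np.random.default_rng(seed)
    per = hz * series.epoch_s
    theta = np.repeat(np.deg2rad(series.z_angle), per)
    norm = np.repeat(1.0 + series.magnitude, per)
    x = norm * np.cos(theta)
    y = np.zeros_like(x)
    zc = norm * np.sin(theta)
    if jitter_g > 0:
        x = x + rng.normal(0, jitter_g, size=len(x))
        y = y + rng.normal(0, jitter_g, size=len(y))
        zc = zc + rng.normal(0, jitter_g, size=len(zc))
    t = series.timestamps[0] + pd.to_timedelta(np.arange(len(x)) * (1.0 / hz), unit="s")
    return pd.DataFrame({"timestamp": t, "x_mean_g": x, "y_mean_g": y, "z_mean_g": zc})


def write_epochs_csv(series: EpochSeries, path: str | Path) -> None:
    """Write the epoch-mode CSV dialect: timestamp,z_angle_deg,magnitude_g,wear."""
    df = pd.DataFrame(
        {
            "timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "z_angle_deg": series.z_angle,
            "magnitude_g": series.magnitude,
            "wear": series.wear.astype(int),
        }
    )
    df.to_csv(path, index=False)


def _ival_str(intervals: Iterable[tuple[pd.Timestamp, pd.Timestamp]]) -> str:
    return ";".join(f"{s.isoformat()}/{e.isoformat()}" for s, e in intervals)


def truth_to_frame(truths: Sequence[TruthDiary]) -> pd.DataFrame:
    rows = []
    for diary in truths:
        for night in diary.nights:
            rows.append(
                {
                    "individual_id": diary.individual_id,
                    "night_index": night.night_index,
                    "spt_start": night.spt_start.isoformat(),
                    "spt_end": night.spt_end.isoformat(),
                    "sleep_duration_h": night.sleep_duration_hours,
                    "n_episodes": len(night.episodes),
                    "episodes": _ival_str(night.episodes),
                    "naps": _ival_str(night.naps),
                    "nonwear": _ival_str(night.nonwear),
                    "l5_midpoint": night.l5_midpoint,
                    "m10_midpoint": night.m10_midpoint,
                }
            )
    return pd.DataFrame(rows)


def write_truth_tsv(truths: Sequence[TruthDiary], path: str | Path) -> None:
    truth_to_frame(truths).to_csv(path, sep="\t", index=False)
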