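"""Per-epoch posture/movement features consumed by the sleep detector.

The detector operates on a *change metric*: the centred rolling median (5-min
window by default) of the absolute successive change in the z-angle.  Edge
windows shrink to the available samples.  The metric series is re-aligned to
the epoch grid of its source recording by letting the first epoch inherit the
first computed value (there is no change *into* epoch 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_cohort import EpochSeries

__all__ = [
    "ChangeMetricSeries",
    "z_angle",
    "abs_change",
    "rolling_median",
    "change_metric",
    "aggregate_raw_to_epochs",
    "read_epochs_csv",
    "UndefinedOrientationError",
    "EpochCsvError",
]


class UndefinedOrientationError(ValueError):
    """All-zero acceleration vector: the z-angle is undefined."""


class EpochCsvError(ValueError):
    """Schema violation in an epoch CSV file (message carries line numbers)."""


@dataclass
class ChangeMetricSeries:
    """Rolling-median absolute z-angle change, degrees per epoch step.

    Same length and timestamp alignment as the source :class:`EpochSeries`.
    """

    timestamps: pd.DatetimeIndex
    value: np.ndarray
    epoch_s: int

    def __post_init__(self) -> None:
        if len(self.timestamps) != len(self.value):
            raise ValueError("timestamps and value must share one length")


def z_angle(x, y, z, on_zero: str = "raise"):
    """Angle of the z axis against the horizontal plane, in degrees.

    ``atan(z / sqrt(x^2 + y^2))`` expressed in degrees, in [-90, 90].
    Invariant to positive scaling of the input vector.

    Parameters
    ----------
    x, y, z : scalar or array-like, acceleration in g.
    on_zero : "raise" to reject all-zero vectors, "propagate" to carry the
        last valid angle forward (leading invalid entries become 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    horiz = np.hypot(x, y)
    invalid = (horiz == 0.0) & (z == 0.0)
    if np.any(invalid):
        if on_zero == "raise":
            raise UndefinedOrientationError("z-angle undefined for all-zero acceleration vector")
        if on_zero != "propagate":
            raise ValueError(f"unknown on_zero policy: {on_zero!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ang = np.degrees(np.arctan2(z, horiz))
    # arctan2 with horiz >= 0 already lands in [-90, 90]
    if np.any(invalid):
        ang = np.where(invalid, np.nan, ang)
        if ang.ndim == 0:
            return 0.0  # nothing valid to propagate from
        ang = pd.Series(ang).ffill().fillna(0.0).to_numpy()
    if ang.ndim == 0:
        return float(ang)
    return ang


def abs_change(z_angles: np.ndarray) -> np.ndarray:
    """Absolute successive z-angle difference; length n-1, aligned to the
    *later* epoch (value[i] is the change into epoch i+1)."""
    z_angles = np.asarray(z_angles, dtype=float)
    if z_angles.size < 2:
        raise ValueError("abs_change needs at least two epochs")
    return np.abs(np.diff(z_angles))


def rolling_median(values: np.ndarray, window: int) -> np.ndarray:
    """Centred rolling median with shrinking edge windows.

    The window at index i covers ``[i - (window - 1) // 2, i + window // 2]``
    clipped to the series; output has the same length as the input.  This
    convention (extra element on the right for even windows) is fixed so that
    results are bit-exact and testable against a brute-force oracle.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window ({window}) longer than series ({n})")
    left = (window - 1) // 2
    right = window // 2
    out = np.empty(n, dtype=float)
    if n >= window:
        interior = np.lib.stride_tricks.sliding_window_view(values, window)
        out[left : left + interior.shape[0]] = np.median(interior, axis=1)
    for i in range(min(left, n)):
        out[i] = np.median(values[: i + right + 1])
    for i in range(max(n - right, 0), n):
        out[i] = np.median(values[i - left :])
    return out


def change_metric(series: EpochSeries, window_minutes: float = 5.0) -> ChangeMetricSeries:
    """Full feature pipeline: abs successive change -> centred rolling median,
    re-aligned to the source epoch grid (epoch 0 inherits the first value)."""
    window = int(round(window_minutes * 60.0 / series.epoch_s))
    if window < 1:
        raise ValueError("window shorter than one epoch")
    diffs = abs_change(series.z_angle)
    smooth = rolling_median(diffs, window)
    value = np.concatenate([[smooth[0]], smooth])
    return ChangeMetricSeries(timestamps=series.timestamps, value=value, epoch_s=series.epoch_s)


def aggregate_raw_to_epochs(
    raw: pd.DataFrame, epoch_s: int, individual_id: str = "raw", on_zero: str = "propagate"
) -> EpochSeries:
    """Aggregate raw tri-axial samples to epoch resolution.

    Per epoch: mean of each axis, then the z-angle of the mean vector;
    magnitude is the per-sample ENMO (``sqrt(x^2+y^2+z^2) - 1`` floored at 0)
    averaged within the epoch.  Epochs with no samples are marked non-wear.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    required = {"timestamp", "x_mean_g", "y_mean_g", "z_mean_g"}
    missing = required - set(raw.columns)
    if missing:
        raise EpochCsvError(f"raw frame missing columns: {sorted(missing)}")
    t = pd.DatetimeIndex(raw["timestamp"])
    if not t.is_monotonic_increasing:
        raise ValueError("raw sample timestamps must be sorted")
    t0 = t[0].floor(f"{epoch_s}s")
    bins = ((t.asi8 - t0.value) // (epoch_s * 1_000_000_000)).astype(np.int64)
    n_epochs = int(bins[-1]) + 1
    frame = pd.DataFrame(
        {
            "bin": bins,
            "x": raw["x_mean_g"].to_numpy(float),
            "y": raw["y_mean_g"].to_numpy(float),
            "z": raw["z_mean_g"].to_numpy(float),
        }
    )
    frame["enmo"] = np.maximum(np.sqrt(frame.x**2 + frame.y**2 + frame.z**2) - 1.0, 0.0)
    g = frame.groupby("bin").agg(x=("x", "mean"), y=("y", "mean"), z=("z", "mean"), enmo=("enmo", "mean"))
    angle = np.zeros(n_epochs, dtype=float)
    mag = np.zeros(n_epochs, dtype=float)
    wear = np.zeros(n_epochs, dtype=bool)
    idx = g.index.to_numpy()
    angle_vals = z_angle(g.x.to_numpy(), g.y.to_numpy(), g.z.to_numpy(), on_zero=on_zero)
    angle[idx] = angle_vals
    mag[idx] = g.enmo.to_numpy()
    wear[idx] = True
    timestamps = pd.DatetimeIndex(t0 + pd.to_timedelta(np.arange(n_epochs) * epoch_s, unit="s"))
    return EpochSeries(
        individual_id=individual_id,
        timestamps=timestamps,
        z_angle=angle,
        magnitude=mag,
        wear=wear,
        epoch_s=epoch_s,
    )


_EPOCH_COLUMNS = ["timestamp", "z_angle_deg", "magnitude_g", "wear"]


def read_epochs_csv(path: str | Path, individual_id: str | None = None) -> EpochSeries:
    """Read the epoch CSV dialect written by the generator, with strict
    schema validation and line-numbered error messages."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise EpochCsvError(f"{path.name}: missing columns {missing}")
    try:
        timestamps = pd.DatetimeIndex(pd.to_datetime(df["timestamp"], format="ISO8601"))
    except (ValueError, TypeError) as exc:
        raise EpochCsvError(f"{path.name}: unparseable timestamp ({exc})") from exc
    for col in ("z_angle_deg", "magnitude_g"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy())[0]
        if bad.size:
            raise EpochCsvError(f"{path.name}: non-numeric {col} at line {bad[0] + 2}")
        df[col] = vals
    z = df["z_angle_deg"].to_numpy(float)
    out_of_range = np.nonzero((z < -90.0) | (z > 90.0))[0]
    if out_of_range.size:
        raise EpochCsvError(f"{path.name}: z_angle_deg out of [-90, 90] at line {out_of_range[0] + 2}")
    mag = df["magnitude_g"].to_numpy(float)
    neg = np.nonzero(mag < 0)[0]
    if neg.size:
        raise EpochCsvError(f"{path.name}: negative magnitude_g at line {neg[0] + 2}")
    deltas = np.diff(timestamps.asi8) // 1_000_000_000
    if deltas.size == 0:
        raise EpochCsvError(f"{path.name}: empty recording")
    step = int(deltas[0])
    irregular = np.nonzero(deltas != step)[0]
    if irregular.size:
        raise EpochCsvError(f"{path.name}: irregular epoch spacing at line {irregular[0] + 3}")
    series = EpochSeries(
        individual_id=individual_id or path.stem.replace(".epochs", ""),
        timestamps=timestamps,
        z_angle=z,
        magnitude=mag,
        wear=df["wear"].astype(bool).to_numpy(),
        epoch_s=step,
    )
    return series
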