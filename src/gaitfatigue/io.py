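"""IMU stream I/O, axis conventions, analysis windows, baseline-relative angles.

A recording holds nine uniformly sampled channels from a heel-mounted
inertial unit: linear accelerations ``ax, ay, az`` in g, angular velocities
``wx, wy, wz`` in degrees/second, and fused orientation angles
``gx, gy, gz`` in degrees. The x axis is medial-lateral, y is
anterior-posterior, and z is vertical. Device full-scale ranges are
+-16 g for acceleration, +-2000 deg/s for angular velocity, and
(-180, 180] degrees for the x/z angles, [-90, 90) for the y angle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import BoundsError, ImuFormatError, SampleRateError

logger = logging.getLogger(__name__)

#: Canonical channel order used everywhere in the package.
CHANNELS: tuple[str, ...] = ("ax", "ay", "az", "wx", "wy", "wz", "gx", "gy", "gz")
ACCEL_CHANNELS = CHANNELS[0:3]
GYRO_CHANNELS = CHANNELS[3:6]
ANGLE_CHANNELS = CHANNELS[6:9]

#: CSV column names (with units) in file order; first column is time.
TIME_COLUMN = "time_s"
CSV_COLUMNS: dict[str, str] = {
    "ax": "ax_g", "ay": "ay_g", "az": "az_g",
    "wx": "wx_dps", "wy": "wy_dps", "wz": "wz_dps",
    "gx": "gx_deg", "gy": "gy_deg", "gz": "gz_deg",
}

#: Device full-scale limits (symmetric) for clipping.
ACCEL_FULL_SCALE_G = 16.0
GYRO_FULL_SCALE_DPS = 2000.0

#: Labels of the three repeated-measures analysis windows.
WINDOW_LABELS: tuple[str, str, str] = ("baseline", "min30", "min60")


def wrap_angle_180(a):
    """Wrap angles (deg) to (-180, 180]."""
    a = np.asarray(a, dtype=float)
    return -((-a + 180.0) % 360.0 - 180.0)


def wrap_angle_90(a):
    """Wrap angles (deg) to [-90, 90) via period 180."""
    a = np.asarray(a, dtype=float)
    return (a + 90.0) % 180.0 - 90.0


def circular_mean_deg(a) -> float:
    """Circular mean of angles in degrees (atan2 of averaged sin/cos)."""
    rad = np.deg2rad(np.asarray(a, dtype=float))
    return float(np.rad2deg(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))))


@dataclass
class ImuRecording:
    """Uniformly sampled 9-channel inertial time series.

    ``data`` has shape ``(9, n_samples)`` with rows in :data:`CHANNELS`
    order. ``t0`` is the timestamp of the first sample in seconds.
    """

    sample_rate: float
    data: np.ndarray
    subject_id: str = ""
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(CHANNELS):
            raise ValueError(
                f"data must have shape (9, n_samples); got {self.data.shape}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        """Return one channel by name (a view into ``data``)."""
        return self.data[CHANNELS.index(name)]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate


@dataclass(frozen=True)
class WindowSpec:
    """Half-open analysis window [start_s, end_s) within a recording."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("window end must exceed start")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def analysis_windows(
    minutes: Sequence[int] = (1, 30, 60), window_s: float = 60.0
) -> list[WindowSpec]:
    """Build the three analysis windows from 1-based minute indices.

    Minute ``m`` covers ``[(m-1)*60, (m-1)*60 + window_s)`` seconds; the
    default ``(1, 30, 60)`` yields the baseline (first), 30th and 60th
    minutes of a one-hour bout. Labels follow :data:`WINDOW_LABELS`
    regardless of the minute values, so scaled-down bouts keep the same
    three-window roles.
    """
    if len(minutes) != 3:
        raise ValueError("exactly three analysis windows are required")
    if sorted(minutes) != list(minutes):
        raise ValueError("window minutes must be increasing")
    return [
        WindowSpec(label, (m - 1) * 60.0, (m - 1) * 60.0 + window_s)
        for label, m in zip(WINDOW_LABELS, minutes)
    ]


def extract_window(recording: ImuRecording, spec: WindowSpec) -> ImuRecording:
    """Slice the half-open sample range covering ``spec``.

    Sample indices are ``[round(start*fs), round(end*fs))`` relative to the
    recording start, so a 60 s window at 50 Hz has exactly 3000 samples.
    """
    fs = recording.sample_rate
    i0 = int(round((spec.start_s - recording.t0) * fs))
    i1 = int(round((spec.end_s - recording.t0) * fs))
    if i0 < 0 or i1 > recording.n_samples:
        raise BoundsError(
            f"window {spec.label} [{spec.start_s}, {spec.end_s}) s exceeds "
            f"recording extent of {recording.duration_s:.2f} s"
        )
    return ImuRecording(
        sample_rate=fs,
        data=recording.data[:, i0:i1].copy(),
        subject_id=recording.subject_id,
        t0=spec.start_s,
        meta={**recording.meta, "window": spec.label, "window_start_index": i0},
    )


def relative_angles(
    recording: ImuRecording, baseline_span_s: float = 30.0
) -> ImuRecording:
    """Re-express orientation channels relative to the walk-in baseline.

    The mean orientation over the first ``baseline_span_s`` seconds is
    subtracted from each angle channel: gx and gz (range +-180 deg) use the
    circular mean and the differences are wrapped back to (-180, 180];
    gy (range +-90 deg, cannot wrap) uses the arithmetic mean with results
    wrapped to [-90, 90). Acceleration and angular velocity are unchanged.
    """
    n_base = int(round(baseline_span_s * recording.sample_rate))
    if recording.n_samples < n_base:
        raise ValueError(
            f"recording ({recording.duration_s:.1f} s) shorter than the "
            f"{baseline_span_s:.0f} s orientation baseline"
        )
    data = recording.data.copy()
    for name in ANGLE_CHANNELS:
        idx = CHANNELS.index(name)
        chan = data[idx]
        if name == "gy":
            data[idx] = wrap_angle_90(chan - np.mean(chan[:n_base]))
        else:
            data[idx] = wrap_angle_180(chan - circular_mean_deg(chan[:n_base]))
    return ImuRecording(
        sample_rate=recording.sample_rate,
        data=data,
        subject_id=recording.subject_id,
        t0=recording.t0,
        meta={**recording.meta, "angles_relative_to_baseline_s": baseline_span_s},
    )


def read_imu_csv(
    path, sample_rate: float = 50.0, subject_id: str | None = None
) -> ImuRecording:
    """Read a delimited IMU stream into a validated :class:`ImuRecording`.

    The file must carry a header naming :data:`TIME_COLUMN` and the nine
    channel columns of :data:`CSV_COLUMNS`. Rows with unparsable numerics
    are dropped with their 1-based line numbers logged. Irregular
    timestamps are tolerated as long as the median inter-sample interval
    matches ``1/sample_rate`` within 10%.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ImuFormatError(f"{path}: empty file") from exc
    missing = [
        col for col in (TIME_COLUMN, *CSV_COLUMNS.values()) if col not in frame.columns
    ]
    if missing:
        raise ImuFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if frame.empty:
        raise ImuFormatError(f"{path}: no data rows")

    numeric = frame[[TIME_COLUMN, *CSV_COLUMNS.values()]].apply(
        pd.to_numeric, errors="coerce"
    )
    bad = numeric.isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based counting.
        lines = [int(i) + 2 for i in numeric.index[bad]]
        logger.warning("%s: dropped %d unparsable row(s) at lines %s",
                       path, len(lines), lines)
        numeric = numeric[~bad]
    if numeric.empty:
        raise ImuFormatError(f"{path}: no parsable data rows")

    t = numeric[TIME_COLUMN].to_numpy()
    if len(t) > 1:
        median_dt = float(np.median(np.diff(t)))
        expected = 1.0 / sample_rate
        if not (0.9 * expected <= median_dt <= 1.1 * expected):
            raise SampleRateError(
                f"{path}: median sample interval {median_dt:.4f} s deviates "
                f"more than 10% from 1/{sample_rate:g} s"
            )
    data = np.vstack([numeric[CSV_COLUMNS[ch]].to_numpy() for ch in CHANNELS])
    return ImuRecording(
        sample_rate=sample_rate,
        data=data,
        subject_id=subject_id if subject_id is not None else path.stem,
        t0=float(t[0]),
        meta={"source": str(path)},
    )


def write_imu_csv(recording: ImuRecording, path, float_format: str = "%.6f") -> None:
    """Write a recording in the package's CSV dialect (UTF-8, '.' decimal)."""
    frame = pd.DataFrame({TIME_COLUMN: recording.times})
    for ch in CHANNELS:
        frame[CSV_COLUMNS[ch]] = recording.channel(ch)
    frame.to_csv(path, index=False, float_format=float_format)


def write_strikes(strikes: Iterable[int], sample_rate: float, path) -> None:
    """Write heel-strike events as a two-column sidecar (index, seconds)."""
    strikes = np.asarray(list(strikes), dtype=int)
    pd.DataFrame(
        {"strike_index": strikes, "time_s": strikes / sample_rate}
    ).to_csv(path, index=False)


def read_strikes(path) -> np.ndarray:
    """Read a strike sidecar back as an integer sample-index array."""
    return pd.read_csv(path)["strike_index"].to_numpy(dtype=int)
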