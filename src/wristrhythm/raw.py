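"""Raw triaxial accelerometer ingestion and conversion to activity counts.

Raw wrist recordings (nominally 50 Hz, acceleration in g) are bandpass
filtered per axis to isolate voluntary movement, combined into a per-sample
vector magnitude, and aggregated into fixed-length epochs (default 30 s).
The static gravity component is removed by the filter's high-pass edge, so a
motionless wrist yields counts near zero regardless of orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd
from scipy import signal

from .series import DEFAULT_COMPLETENESS_THRESHOLD, EpochCountSeries

__all__ = ["RawAccelRecording", "read_raw_recording", "compute_epoch_counts"]

RAW_COLUMNS = ["t_s", "x_g", "y_g", "z_g"]

# default passband for wrist movement, Hz
DEFAULT_LOW_HZ = 0.25
DEFAULT_HIGH_HZ = 3.0
DEFAULT_FILTER_ORDER = 4


@dataclass
class RawAccelRecording:
    """A triaxial acceleration stream with strictly increasing sample times.

    ``sample_times`` are seconds since recording start; ``start_clock_time``
    anchors them to the local clock. ``gaps`` lists (start_s, end_s) intervals
    with no samples, found at ingestion.
    """

    sample_times: np.ndarray
    accel_x: np.ndarray
    accel_y: np.ndarray
    accel_z: np.ndarray
    participant_id: str
    start_clock_time: datetime
    nominal_hz: float
    gaps: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.sample_times)

    @property
    def duration_s(self) -> float:
        return float(self.sample_times[-1] - self.sample_times[0])


def read_raw_recording(
    path,
    clock_origin: datetime,
    participant_id: str = "",
    nominal_hz: float | None = None,
    monotone_tol_s: float = 1e-6,
    gap_factor: float = 5.0,
) -> RawAccelRecording:
    """Read a delimited raw-sample file (columns ``t_s,x_g,y_g,z_g``).

    Duplicate timestamps are collapsed by averaging the axis values. Sample
    times must be nondecreasing within ``monotone_tol_s``. The nominal rate
    is estimated from the median inter-sample interval unless given, and must
    lie in [25, 200] Hz. Intervals longer than ``gap_factor`` median steps
    are recorded as gaps.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"raw file missing required columns {missing_cols}")
    if len(df) == 0:
        raise ValueError("no samples")
    numeric = df[RAW_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) | ~np.isfinite(numeric.to_numpy()).all(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"unparseable or non-finite raw sample at line {line}")
    t = numeric["t_s"].to_numpy()
    if np.any(np.diff(t) < -monotone_tol_s):
        line = int(np.flatnonzero(np.diff(t) < -monotone_tol_s)[0]) + 2
        raise ValueError(f"non-monotone sample times at line {line}")

    # collapse duplicate timestamps by averaging
    grouped = numeric.groupby("t_s", sort=True).mean()
    t = grouped.index.to_numpy()
    if len(t) < 2:
        raise ValueError("need at least 2 distinct sample times")
    dt = np.diff(t)
    med_dt = float(np.median(dt))
    if med_dt <= 0:
        raise ValueError("degenerate sample spacing")
    rate = nominal_hz if nominal_hz is not None else 1.0 / med_dt
    if not 25.0 <= rate <= 200.0:
        raise ValueError(f"nominal rate {rate:.1f} Hz outside supported range [25, 200]")

    gap_thresh = gap_factor * med_dt
    gap_idx = np.flatnonzero(dt > gap_thresh)
    gaps = [(float(t[i]), float(t[i + 1])) for i in gap_idx]

    return RawAccelRecording(
        sample_times=t,
        accel_x=grouped["x_g"].to_numpy(),
        accel_y=grouped["y_g"].to_numpy(),
        accel_z=grouped["z_g"].to_numpy(),
        participant_id=participant_id,
        start_clock_time=clock_origin,
        nominal_hz=float(rate),
        gaps=gaps,
    )


def _bandpass_sos(low_hz: float, high_hz: float, order: int, fs: float):
    nyq = fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"invalid band edges: need 0 < {low_hz} < {high_hz} < Nyquist ({nyq})"
        )
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def compute_epoch_counts(
    rec: RawAccelRecording,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    filter_order: int = DEFAULT_FILTER_ORDER,
    epoch_s: int = 30,
    completeness_threshold: float = DEFAULT_COMPLETENESS_THRESHOLD,
    rate_tolerance: float = 0.10,
) -> EpochCountSeries:
    """Bandpass-filter a raw recording and aggregate into epoch counts.

    Each axis is filtered with a zero-phase Butterworth bandpass
    (``sosfiltfilt``); the per-sample Euclidean norm of the filtered axes is
    averaged within each epoch and scaled by the epoch length in seconds to
    give the count. Epoch grid starts at the clock boundary at or before the
    first sample. Epochs observing fewer than ``completeness_threshold`` of
    the expected samples are marked missing (NaN).
    """
    if 60 % epoch_s != 0:
        raise ValueError("epoch_s must divide 60")
    if rec.duration_s < epoch_s:
        raise ValueError("recording shorter than one epoch")
    dt = np.diff(rec.sample_times)
    med_dt = float(np.median(dt))
    if abs(med_dt - 1.0 / rec.nominal_hz) > rate_tolerance / rec.nominal_hz:
        raise ValueError(
            "median inter-sample interval deviates more than "
            f"{rate_tolerance:.0%} from nominal {rec.nominal_hz} Hz; "
            "resample before ingestion"
        )
    sos = _bandpass_sos(low_hz, high_hz, filter_order, rec.nominal_hz)
    fx = signal.sosfiltfilt(sos, rec.accel_x)
    fy = signal.sosfiltfilt(sos, rec.accel_y)
    fz = signal.sosfiltfilt(sos, rec.accel_z)
    norm = np.sqrt(fx**2 + fy**2 + fz**2)

    origin = pd.Timestamp(rec.start_clock_time)
    # align grid to clock epoch boundaries
    grid_start = origin.floor(f"{epoch_s}s")
    offset_s = (origin - grid_start).total_seconds()
    sample_clock = rec.sample_times - rec.sample_times[0] + offset_s
    epoch_idx = np.floor(sample_clock / epoch_s).astype(np.int64)
    n_epochs = int(epoch_idx[-1]) + 1

    sums = np.bincount(epoch_idx, weights=norm, minlength=n_epochs)
    n_in = np.bincount(epoch_idx, minlength=n_epochs).astype(float)
    expected = rec.nominal_hz * epoch_s
    observed_fraction = np.clip(n_in / expected, 0.0, 1.0)
    with np.errstate(invalid="ignore"):
        counts = np.where(n_in > 0, sums / np.maximum(n_in, 1) * epoch_s, np.nan)
    counts = np.where(observed_fraction < completeness_threshold, np.nan, counts)

    times = pd.date_range(grid_start, periods=n_epochs, freq=f"{epoch_s}s")
    return EpochCountSeries(
        epoch_start_times=times,
        counts=counts,
        observed_fraction=observed_fraction,
        epoch_s=epoch_s,
    )
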