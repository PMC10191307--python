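"""Raw-signal preprocessing into aligned 30-s epoch series.

Covers the wearable/PSG-derived input paths: R-point trains to per-epoch
heart-rate mean (HRM) and standard deviation (HRSD) with artifact
correction and outlier rejection, 60-s activity upsampling, z-axis
accelerometry to activity counts, and cross-correlation alignment of the
activity and cardiac channels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .stages import Hypnogram

log = logging.getLogger(__name__)

# physiologic interval bounds (s): below 0.33 s is >180 bpm, above 1.33 s
# is <46 bpm; both treated as detection artifacts
SHORT_INTERVAL_S = 0.33
LONG_INTERVAL_S = 1.33


@dataclass
class RPeakTrain:
    """R-point timestamps in seconds from recording start."""

    timestamps: np.ndarray

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        if self.timestamps.ndim != 1:
            raise ValueError("timestamps must be one-dimensional")
        if self.timestamps.size and self.timestamps[0] < 0:
            raise ValueError("timestamps must be nonnegative")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("R-peak timestamps must be strictly increasing")

    def __len__(self):
        return self.timestamps.size


@dataclass
class EpochIHR:
    """Instantaneous-heart-rate values grouped by 30-s epoch."""

    values: list[np.ndarray]  # bpm, one array per epoch
    epoch_s: float = 30.0


@dataclass
class EpochSeries:
    """One subject-night of aligned per-epoch channels."""

    subject_id: str
    activity: np.ndarray          # counts/epoch, >= 0
    hrm: np.ndarray               # bpm
    hrsd: np.ndarray              # bpm
    clock: np.ndarray             # seconds since midnight
    stage: Hypnogram | None = None
    mask: np.ndarray = field(default=None)  # True where valid
    epoch_s: float = 30.0

    def __post_init__(self):
        self.activity = np.asarray(self.activity, dtype=np.float64)
        self.hrm = np.asarray(self.hrm, dtype=np.float64)
        self.hrsd = np.asarray(self.hrsd, dtype=np.float64)
        self.clock = np.asarray(self.clock, dtype=np.float64)
        n = self.activity.size
        if not (self.hrm.size == self.hrsd.size == self.clock.size == n):
            raise ValueError("all channels must have equal length")
        if self.stage is not None and len(self.stage) != n:
            raise ValueError("stage labels must match channel length")
        if self.mask is None:
            self.mask = np.isfinite(self.hrm) & np.isfinite(self.activity)
        self.mask = np.asarray(self.mask, dtype=bool)

    def __len__(self):
        return self.activity.size


# ---------------------------------------------------------------------------
# R-peak / IHR pipeline
# ---------------------------------------------------------------------------

def intervals_from_rpeaks(train: RPeakTrain | np.ndarray) -> np.ndarray:
    """Consecutive R-R intervals in seconds; empty for fewer than 2 peaks."""
    if not isinstance(train, RPeakTrain):
        train = RPeakTrain(np.asarray(train))
    if len(train) < 2:
        return np.empty(0)
    return np.diff(train.timestamps)


def assign_epochs(train: RPeakTrain, epoch_s: float = 30.0) -> np.ndarray:
    """Epoch index of each interval, by its terminating R-peak.

    Epoch windows are half-open [t, t + epoch_s).
    """
    return np.floor(train.timestamps[1:] / epoch_s).astype(np.int64)


def correct_intervals(intervals: np.ndarray,
                      epoch_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Apply the short/long R-R interval artifact correction.

    Intervals below 0.33 s (spurious beats) are replaced by the midpoint
    (arithmetic mean) of the interval and its predecessor. Intervals above
    1.33 s (missed beats) are replaced by n = max(1, round(T / T_mean))
    equal sub-intervals of length T/n, where T_mean is the mean raw
    interval of the containing epoch. Single pass, in input order.

    Returns (corrected_intervals, corrected_epoch_ids); splitting grows the
    sequence, with sub-intervals inheriting the source epoch.
    """
    intervals = np.asarray(intervals, dtype=np.float64)
    epoch_ids = np.asarray(epoch_ids, dtype=np.int64)
    if intervals.size != epoch_ids.size:
        raise ValueError("intervals and epoch assignment differ in length")
    if intervals.size == 0:
        return intervals.copy(), epoch_ids.copy()
    if np.any(intervals <= 0):
        raise ValueError("intervals must be positive")

    # per-epoch mean over *raw* intervals
    t_mean: dict[int, float] = {}
    for e in np.unique(epoch_ids):
        t_mean[int(e)] = float(intervals[epoch_ids == e].mean())

    out: list[float] = []
    out_epochs: list[int] = []
    prev: float | None = None
    for t, e in zip(intervals, epoch_ids):
        if t < SHORT_INTERVAL_S:
            if prev is None:
                log.warning("short first interval %.3f s: no predecessor, "
                            "falling back to epoch mean", t)
                repl = t_mean[int(e)]
            else:
                repl = 0.5 * (t + prev)
            out.append(repl)
            out_epochs.append(int(e))
            prev = repl
        elif t > LONG_INTERVAL_S:
            if prev is None:
                log.warning("long first interval %.3f s: no predecessor, "
                            "falling back to epoch mean", t)
            n = max(1, int(round(t / t_mean[int(e)])))
            out.extend([t / n] * n)
            out_epochs.extend([int(e)] * n)
            prev = t / n
        else:
            out.append(float(t))
            out_epochs.append(int(e))
            prev = float(t)
    return np.array(out), np.array(out_epochs, dtype=np.int64)


def ihr_from_rpeaks(train: RPeakTrain, n_epochs: int | None = None,
                    epoch_s: float = 30.0, correct: bool = True) -> EpochIHR:
    """Instantaneous heart rate (bpm) per epoch from an R-peak train.

    IHR is the reciprocal of each (artifact-corrected) R-R interval.
    """
    ivals = intervals_from_rpeaks(train)
    if ivals.size == 0:
        return EpochIHR([np.empty(0)] * (n_epochs or 0), epoch_s)
    epochs = assign_epochs(train, epoch_s)
    if correct:
        ivals, epochs = correct_intervals(ivals, epochs)
    if n_epochs is None:
        n_epochs = int(epochs.max()) + 1
    ihr = 60.0 / ivals
    values = [ihr[epochs == e] for e in range(n_epochs)]
    return EpochIHR(values, epoch_s)


def epoch_hr_stats(values: np.ndarray) -> tuple[float, float]:
    """HRM/HRSD of one epoch with single-pass 2-SD outlier rejection.

    Mean and sample SD are computed over the epoch's IHR values, values
    outside mean +/- 2 SD are discarded, and HRM/HRSD recomputed on the
    survivors. Empty epochs return (nan, nan) for masking downstream.
    """
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return (np.nan, np.nan)
    if v.size == 1:
        return (float(v[0]), 0.0)
    m, s = v.mean(), v.std(ddof=1)
    keep = np.abs(v - m) <= 2.0 * s
    v = v[keep]
    if v.size == 0:  # unreachable for >=2 values, kept for safety
        return (np.nan, np.nan)
    if v.size == 1:
        return (float(v[0]), 0.0)
    return (float(v.mean()), float(v.std(ddof=1)))


def hr_channels_from_rpeaks(train: RPeakTrain, n_epochs: int,
                            epoch_s: float = 30.0,
                            correct: bool = True) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-epoch (hrm, hrsd, valid_mask) arrays from an R-peak train."""
    by_epoch = ihr_from_rpeaks(train, n_epochs, epoch_s, correct=correct)
    hrm = np.full(n_epochs, np.nan)
    hrsd = np.full(n_epochs, np.nan)
    for e, vals in enumerate(by_epoch.values):
        hrm[e], hrsd[e] = epoch_hr_stats(vals)
    return hrm, hrsd, np.isfinite(hrm)


# ---------------------------------------------------------------------------
# Activity channels
# ---------------------------------------------------------------------------

def upsample_activity(counts_60s: np.ndarray) -> np.ndarray:
    """60-s activity counts to 30-s resolution by adjacent replication."""
    return np.repeat(np.asarray(counts_60s, dtype=np.float64), 2)


def accel_to_counts(z_signal: np.ndarray, fs: float,
                    band: tuple[float, float] = (0.5, 3.5), order: int = 4,
                    n_bins: int = 128, max_g: float = 2.0,
                    window_s: float = 15.0) -> np.ndarray:
    """z-axis accelerometry to activity counts per 15-s epoch.

    A Butterworth band-pass removes the gravitational/rotation component;
    the absolute filtered amplitude is quantized into ``n_bins`` uniform
    bins over [0, max_g] and bin indices are summed over each window. The
    band edges and binning are configurable conventions, not fixed device
    constants.
    """
    z = np.asarray(z_signal, dtype=np.float64)
    lo, hi = band
    if fs <= 2 * hi:
        raise ValueError(f"sampling rate {fs} Hz too low for band edge {hi} Hz")
    samples_per_win = int(round(window_s * fs))
    if z.size < samples_per_win:
        return np.empty(0)
    pad = min(3 * order * int(fs), z.size - 1)
    sos = _signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filt = _signal.sosfiltfilt(sos, z, padlen=pad)
    bins = np.clip(np.floor(np.abs(filt) / max_g * n_bins), 0, n_bins - 1)
    n_win = z.size // samples_per_win
    return bins[: n_win * samples_per_win].reshape(n_win, samples_per_win).sum(axis=1)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_by_crosscorr(activity: np.ndarray, hr: np.ndarray,
                       max_lag: int = 10) -> tuple[int, np.ndarray, np.ndarray]:
    """Lag (epochs) maximizing the cross-correlation, plus trimmed series.

    Positive lag means ``hr`` lags ``activity`` by that many epochs, i.e.
    activity[t] aligns with hr[t + lag]. Returns (lag, activity_aligned,
    hr_aligned) trimmed to the overlapping span.
    """
    a = np.asarray(activity, dtype=np.float64)
    b = np.asarray(hr, dtype=np.float64)
    if a.size < 2 * max_lag or b.size < 2 * max_lag:
        raise ValueError("series too short for the requested maximum lag")
    a0, b0 = a - a.mean(), b - b.mean()
    if a0.std() == 0 or b0.std() == 0:
        warnings.warn("zero-variance input to alignment; returning lag 0")
        lag = 0
    else:
        lags = np.arange(-max_lag, max_lag + 1)
        cc = np.empty(lags.size)
        for i, k in enumerate(lags):
            if k >= 0:
                x, y = a0[: a0.size - k], b0[k: k + a0.size - k]
            else:
                x, y = a0[-k:], b0[: b0.size + k]
            n = min(x.size, y.size)
            cc[i] = float(np.dot(x[:n], y[:n]))
        lag = int(lags[np.argmax(cc)])
    if lag >= 0:
        a_al, b_al = a[: a.size - lag] if lag else a, b[lag:]
    else:
        a_al, b_al = a[-lag:], b[: b.size + lag]
    n = min(a_al.size, b_al.size)
    return lag, a_al[:n], b_al[:n]
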