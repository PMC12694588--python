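"""Time- and frequency-domain heart-rate-variability measures.

Input is an artifact-masked series of normal-to-normal (NN) inter-beat
intervals.  Intervals flagged invalid (artifact segments marked by an
upstream rater or injector) are excluded from every measure: SDNN simply
drops them, RMSSD additionally drops the two successive-difference pairs
adjacent to each gap, and spectral power is computed only over contiguous
valid spans of the tachogram (gaps are never bridged by interpolation).

Frequency-domain power follows the conventional resting HRV bands:
LF 0.04-0.15 Hz, HF 0.15-0.40 Hz.  The tachogram is cubic-spline
interpolated to a uniform grid (10 Hz by default), mean-removed, and an
FFT periodogram is integrated over the band by the rectangle rule.
Absolute power in ms^2 is reported (not normalized units); analyses use
natural-log-transformed measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import periodogram

__all__ = [
    "LF_BAND",
    "HF_BAND",
    "UndefinedMeasureError",
    "NNIntervalSeries",
    "HrvMeasures",
    "sdnn",
    "rmssd",
    "band_power",
    "hrv_measures",
    "log_measures",
    "detect_pulse_peaks",
    "read_nn_csv",
    "write_nn_csv",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


class UndefinedMeasureError(ValueError):
    """An HRV measure is undefined for the given series (too few valid
    intervals, zero raw value under a log transform, or a span too short
    for the requested frequency band)."""


@dataclass(frozen=True)
class NNIntervalSeries:
    """Artifact-masked NN interval series.

    Attributes
    ----------
    onset_times : ndarray, seconds
        Start time of each interval relative to the series origin,
        strictly increasing.
    intervals : ndarray, milliseconds
        NN interval durations; strictly positive where ``valid``.
    valid : ndarray of bool
        False marks intervals overlapping artifact segments; they are
        excluded from all measures but retained so that the temporal
        structure of the series is preserved.
    """

    onset_times: np.ndarray
    intervals: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        onset = np.asarray(self.onset_times, dtype=float)
        intervals = np.asarray(self.intervals, dtype=float)
        valid = self.valid
        if valid is None:
            valid = np.ones(intervals.shape, dtype=bool)
        valid = np.asarray(valid, dtype=bool)
        if not (onset.ndim == intervals.ndim == valid.ndim == 1):
            raise ValueError("onset_times, intervals and valid must be 1-D")
        if not (len(onset) == len(intervals) == len(valid)):
            raise ValueError(
                f"length mismatch: {len(onset)} onsets, {len(intervals)} "
                f"intervals, {len(valid)} validity flags"
            )
        if len(onset) > 1 and not np.all(np.diff(onset) > 0):
            raise ValueError("onset_times must be strictly increasing")
        if np.any(intervals[valid] <= 0):
            raise ValueError("valid intervals must be strictly positive")
        object.__setattr__(self, "onset_times", onset)
        object.__setattr__(self, "intervals", intervals)
        object.__setattr__(self, "valid", valid)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def duration(self) -> float:
        """Total span covered by the series, in seconds."""
        if len(self) == 0:
            return 0.0
        return float(self.onset_times[-1] + self.intervals[-1] / 1000.0)

    def slice_window(self, start_s: float, end_s: float) -> "NNIntervalSeries":
        """Intervals whose onset falls in ``[start_s, end_s)``.

        Onset times stay on the original clock so that windows from the
        same scan remain mutually comparable.
        """
        sel = (self.onset_times >= start_s) & (self.onset_times < end_s)
        return NNIntervalSeries(
            self.onset_times[sel], self.intervals[sel], self.valid[sel]
        )


@dataclass
class HrvMeasures:
    """Raw and natural-log HRV measures for one series (or one window).

    ``sdnn``/``rmssd`` are in ms, ``lf``/``hf`` in ms^2.  Log fields are
    NaN until :func:`log_measures` populates them, and stay NaN for any
    raw value that is not strictly positive.
    """

    sdnn: float
    rmssd: float
    lf: float
    hf: float
    log_sdnn: float = np.nan
    log_rmssd: float = np.nan
    log_lf: float = np.nan
    log_hf: float = np.nan


def sdnn(nn: NNIntervalSeries) -> float:
    """Standard deviation of valid NN intervals (ms), sample divisor n-1."""
    vals = nn.intervals[nn.valid]
    if len(vals) < 2:
        raise UndefinedMeasureError(
            f"SDNN requires >= 2 valid intervals, got {len(vals)}"
        )
    return float(np.std(vals, ddof=1))


def rmssd(nn: NNIntervalSeries) -> float:
    """Root mean square of successive differences over valid pairs (ms).

    A successive pair is two adjacent intervals that are both valid;
    pairs spanning an artifact-marked interval are excluded.
    """
    pair_ok = nn.valid[:-1] & nn.valid[1:]
    if not pair_ok.any():
        raise UndefinedMeasureError("RMSSD requires >= 1 valid successive pair")
    d = np.diff(nn.intervals)[pair_ok]
    return float(np.sqrt(np.mean(d**2)))


def _valid_spans(nn: NNIntervalSeries) -> list[tuple[np.ndarray, np.ndarray]]:
    """Contiguous runs of valid intervals as (onset, interval) pairs."""
    spans: list[tuple[np.ndarray, np.ndarray]] = []
    idx = np.flatnonzero(nn.valid)
    if len(idx) == 0:
        return spans
    breaks = np.flatnonzero(np.diff(idx) > 1)
    for chunk in np.split(idx, breaks + 1):
        spans.append((nn.onset_times[chunk], nn.intervals[chunk]))
    return spans


def band_power(
    nn: NNIntervalSeries,
    band: tuple[float, float],
    interp_rate: float = 10.0,
) -> float:
    """Spectral power of the NN tachogram in ``band`` (ms^2).

    Each contiguous valid span with at least 4 beats is cubic-spline
    interpolated against beat onset times onto a uniform ``interp_rate``
    grid, mean-removed, and its FFT periodogram integrated over
    ``[band[0], band[1])`` by the rectangle rule.  Spans are combined by
    a duration-weighted average; gaps between spans are never bridged.
    """
    low, high = band
    if not (0 < low < high):
        raise ValueError(f"invalid band {band!r}")
    if nn.n_valid < 4:
        raise UndefinedMeasureError(
            f"band power requires >= 4 valid intervals, got {nn.n_valid}"
        )
    min_span = 2.0 / low
    powers: list[float] = []
    weights: list[float] = []
    for onset, ivals in _valid_spans(nn):
        span_len = onset[-1] - onset[0]
        if len(onset) < 4 or span_len < min_span:
            continue
        spline = CubicSpline(onset, ivals)
        n_samp = int(np.floor(span_len * interp_rate)) + 1
        grid = onset[0] + np.arange(n_samp) / interp_rate
        tacho = spline(grid)
        freqs, psd = periodogram(
            tacho, fs=interp_rate, detrend="constant", scaling="density"
        )
        df = freqs[1] - freqs[0]
        in_band = (freqs >= low) & (freqs < high)
        powers.append(float(np.sum(psd[in_band]) * df))
        weights.append(span_len)
    if not powers:
        raise UndefinedMeasureError(
            f"no valid span of >= 4 beats covering {min_span:.0f} s "
            f"(2 cycles of {low} Hz)"
        )
    return float(np.average(powers, weights=weights))


def hrv_measures(
    nn: NNIntervalSeries,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
    interp_rate: float = 10.0,
) -> HrvMeasures:
    """All four HRV measures plus their natural logs for one series."""
    raw = HrvMeasures(
        sdnn=sdnn(nn),
        rmssd=rmssd(nn),
        lf=band_power(nn, lf_band, interp_rate),
        hf=band_power(nn, hf_band, interp_rate),
    )
    return log_measures(raw)


def log_measures(raw: HrvMeasures) -> HrvMeasures:
    """Populate natural-log fields; non-positive raw values yield NaN.

    HRV distributions are right-skewed, so all downstream analyses use
    the log scale.  A zero raw value (e.g. SDNN of a constant series)
    leaves the corresponding log field NaN — the undefined-measure
    signal for that field.
    """

    def _log(x: float) -> float:
        return float(np.log(x)) if x > 0 else np.nan

    return replace(
        raw,
        log_sdnn=_log(raw.sdnn),
        log_rmssd=_log(raw.rmssd),
        log_lf=_log(raw.lf),
        log_hf=_log(raw.hf),
    )


def detect_pulse_peaks(
    waveform: np.ndarray,
    fs: float,
    refractory_s: float = 0.3,
    threshold_quantile: float = 0.6,
) -> np.ndarray:
    """Minimal peak detector for *synthetic* pulse waveforms.

    Local maxima above an adaptive amplitude threshold (a quantile of the
    signal) separated by a refractory period.  This is deliberately
    simple: cleaning of real photoplethysmography is delegated upstream,
    and only simulated waveforms are expected here.

    Returns peak times in seconds.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1 or len(waveform) < 3:
        raise ValueError("waveform must be 1-D with >= 3 samples")
    thresh = np.quantile(waveform, threshold_quantile)
    is_peak = (
        (waveform[1:-1] > waveform[:-2])
        & (waveform[1:-1] >= waveform[2:])
        & (waveform[1:-1] > thresh)
    )
    cand = np.flatnonzero(is_peak) + 1
    keep: list[int] = []
    min_gap = int(round(refractory_s * fs))
    for c in cand:
        if not keep or c - keep[-1] >= min_gap:
            keep.append(int(c))
    return np.asarray(keep, dtype=float) / fs


def read_nn_csv(path: str | Path) -> NNIntervalSeries:
    """Read an NN series from CSV (columns onset_s, interval_ms, valid)."""
    df = pd.read_csv(path)
    return NNIntervalSeries(
        df["onset_s"].to_numpy(float),
        df["interval_ms"].to_numpy(float),
        df["valid"].to_numpy(bool),
    )


def write_nn_csv(nn: NNIntervalSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "onset_s": nn.onset_times,
            "interval_ms": nn.intervals,
            "valid": nn.valid,
        }
    ).to_csv(path, index=False)
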