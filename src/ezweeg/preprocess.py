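"""Artifact suppression and contrast enhancement for EEG segments.

Three operations: zero-phase band-pass (1–70 Hz) plus mains-notch (50 Hz)
filtering, a 1-D adaptive median filter for impulse artifacts, and per-segment
histogram equalization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from ezweeg.signal_io import MultichannelRecording, Segment

__all__ = [
    "FilterSpec",
    "bandpass_notch",
    "adaptive_median_filter",
    "adaptive_mean_filter",
    "histogram_equalize",
]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass + notch design: 1–70 Hz pass band, 50 Hz mains notch."""

    band_low_hz: float = 1.0
    band_high_hz: float = 70.0
    notch_hz: float = 50.0
    notch_q: float = 30.0
    order: int = 4

    def validate(self, sampling_rate_hz: float) -> None:
        nyq = sampling_rate_hz / 2.0
        if not (0 < self.band_low_hz < self.band_high_hz < nyq):
            raise ValueError(
                f"band edges must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
            )
        if not (0 < self.notch_hz < nyq):
            raise ValueError(f"notch must lie below Nyquist ({nyq} Hz)")


def bandpass_notch(
    rec: MultichannelRecording, spec: FilterSpec | None = None
) -> MultichannelRecording:
    """Zero-phase band-pass + notch filtering, per channel.

    Butterworth band-pass (SOS, forward-backward so the phase is zero) followed
    by an IIR notch at the mains frequency.  Output length equals input length.
    """
    if spec is None:
        spec = FilterSpec()
    spec.validate(rec.sampling_rate_hz)
    fs = rec.sampling_rate_hz
    sos = sps.butter(
        spec.order, [spec.band_low_hz, spec.band_high_hz], btype="bandpass", fs=fs, output="sos"
    )
    b_n, a_n = sps.iirnotch(spec.notch_hz, spec.notch_q, fs=fs)
    out = sps.sosfiltfilt(sos, rec.samples, axis=1)
    out = sps.filtfilt(b_n, a_n, out, axis=1)
    return MultichannelRecording(
        samples=out,
        sampling_rate_hz=rec.sampling_rate_hz,
        channel_labels=list(rec.channel_labels),
    )


def filter_values(values: np.ndarray, sampling_rate_hz: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Apply :func:`bandpass_notch` to a bare 1-D sample vector."""
    rec = MultichannelRecording(values[np.newaxis, :], sampling_rate_hz)
    return bandpass_notch(rec, spec).samples[0]


def _window_stats(values: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # reflect-pad so every sample has a full window
    half = w // 2
    padded = np.pad(values, half, mode="reflect")
    win = sliding_window_view(padded, w)
    return np.median(win, axis=1), win.min(axis=1), win.max(axis=1)


def adaptive_median_filter(
    seg: Segment, window_init: int = 3, window_max: int = 9
) -> Segment:
    """1-D adaptive median filter (impulse suppression).

    At each sample the window grows from ``window_init`` until the window
    median lies strictly between the window min and max (or ``window_max`` is
    reached); the sample is replaced by that median only when it equals the
    window min or max, otherwise it is kept.  Edges use reflection.
    """
    _check_windows(window_init, window_max, seg.n)
    values = seg.values
    out = values.copy()
    sizes = list(range(window_init, window_max + 1, 2))
    med = np.empty((len(sizes), seg.n))
    lo = np.empty_like(med)
    hi = np.empty_like(med)
    for i, w in enumerate(sizes):
        med[i], lo[i], hi[i] = _window_stats(values, w)
    ok = (med > lo) & (med < hi)  # median strictly inside the window range
    # first window size whose median is informative; fall back to the largest
    first = np.where(ok.any(axis=0), ok.argmax(axis=0), len(sizes) - 1)
    idx = np.arange(seg.n)
    sel_med = med[first, idx]
    sel_lo = lo[first, idx]
    sel_hi = hi[first, idx]
    impulse = (values == sel_lo) | (values == sel_hi)
    out[impulse] = sel_med[impulse]
    return replace(seg, values=out)


def adaptive_mean_filter(seg: Segment, window_init: int = 3, window_max: int = 9) -> Segment:
    """Mean-based variant of the adaptive filter (replacement uses the window mean)."""
    _check_windows(window_init, window_max, seg.n)
    values = seg.values
    out = values.copy()
    sizes = list(range(window_init, window_max + 1, 2))
    mean = np.empty((len(sizes), seg.n))
    lo = np.empty_like(mean)
    hi = np.empty_like(mean)
    for i, w in enumerate(sizes):
        half = w // 2
        padded = np.pad(values, half, mode="reflect")
        win = sliding_window_view(padded, w)
        mean[i] = win.mean(axis=1)
        lo[i] = win.min(axis=1)
        hi[i] = win.max(axis=1)
    ok = (mean > lo) & (mean < hi)
    first = np.where(ok.any(axis=0), ok.argmax(axis=0), len(sizes) - 1)
    idx = np.arange(seg.n)
    impulse = (values == lo[first, idx]) | (values == hi[first, idx])
    out[impulse] = mean[first, idx][impulse]
    return replace(seg, values=out)


def _check_windows(window_init: int, window_max: int, n: int) -> None:
    if window_init % 2 == 0 or window_max % 2 == 0:
        raise ValueError("window sizes must be odd")
    if not (3 <= window_init <= window_max < n):
        raise ValueError("require 3 <= window_init <= window_max < N")


def histogram_equalize(
    seg: Segment, n_bins: int = 256, on_constant: str = "error"
) -> Segment:
    """Histogram equalization of segment amplitudes.

    Amplitudes are quantized to ``n_bins`` uniform bins over ``[min, max]``,
    mapped through the cumulative histogram, and rescaled back to the original
    amplitude range.  The mapping is monotone nondecreasing.

    ``on_constant`` selects behaviour for a zero-range segment: ``"error"``
    raises, ``"identity"`` returns the segment unchanged.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    v = seg.values
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        if on_constant == "identity":
            return replace(seg, values=v.copy())
        raise ValueError("constant segment has zero amplitude range")
    bins = np.minimum(((v - vmin) / (vmax - vmin) * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins)
    cdf = np.cumsum(counts) / v.size
    out = vmin + cdf[bins] * (vmax - vmin)
    return replace(seg, values=out)
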