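"""Multilevel 1-D discrete wavelet transform for the zerotree codec.

The pyramid uses periodized boundaries so that the coefficient count equals
the sample count exactly — the property the zerotree parent/child structure
relies on.  Default mother wavelet is Daubechies-4 at 3 levels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pywt

from ezweeg.signal_io import Segment

__all__ = [
    "WaveletCoeffs",
    "dwt_multilevel",
    "idwt_multilevel",
    "quantize_coeffs",
    "dequantize_coeffs",
    "band_sizes",
]

DEFAULT_WAVELET = "db4"
DEFAULT_LEVELS = 3
_MODE = "periodization"


@dataclass
class WaveletCoeffs:
    """Coefficient pyramid of a multilevel 1-D DWT.

    ``details`` runs from the coarsest level to the finest.  With periodized
    boundaries ``len(approx) + sum(len(d) for d in details) == original_length``.
    """

    approx: np.ndarray
    details: list[np.ndarray]
    wavelet_name: str = DEFAULT_WAVELET
    original_length: int = 0
    quant_step: float | None = None  # set once quantized; None = raw floats

    def __post_init__(self) -> None:
        self.approx = np.asarray(self.approx, dtype=float)
        self.details = [np.asarray(d, dtype=float) for d in self.details]
        if self.original_length == 0:
            self.original_length = self.total_count

    @property
    def levels(self) -> int:
        return len(self.details)

    @property
    def total_count(self) -> int:
        return self.approx.size + sum(d.size for d in self.details)

    def bands(self) -> list[np.ndarray]:
        """Pyramid as a band list, coarse to fine: [approx, dL, ..., d1]."""
        return [self.approx] + list(self.details)

    def to_array(self) -> np.ndarray:
        return np.concatenate(self.bands())

    @classmethod
    def from_bands(cls, bands: list[np.ndarray], wavelet_name: str,
                   original_length: int, quant_step: float | None = None) -> "WaveletCoeffs":
        return cls(
            approx=bands[0],
            details=list(bands[1:]),
            wavelet_name=wavelet_name,
            original_length=original_length,
            quant_step=quant_step,
        )


def band_sizes(n: int, levels: int) -> list[int]:
    """Band lengths ``[approx, dL, ..., d1]`` for a periodized ``levels``-deep DWT of ``n`` samples."""
    detail: list[int] = []
    cur = n
    for _ in range(levels):
        cur = (cur + 1) // 2  # pywt periodization: ceil(n/2)
        detail.append(cur)
    return [detail[-1]] + detail[::-1]


def dwt_multilevel(
    seg: Segment | np.ndarray,
    levels: int = DEFAULT_LEVELS,
    wavelet_name: str = DEFAULT_WAVELET,
) -> WaveletCoeffs:
    """Standard pyramid decomposition; band lengths halve per level."""
    values = seg.values if isinstance(seg, Segment) else np.asarray(seg, dtype=float)
    n = values.size
    if not (1 <= levels <= int(math.log2(n))):
        raise ValueError(f"levels must lie in [1, floor(log2 {n})]")
    with warnings.catch_warnings():
        # pywt warns when levels exceed its filter-length heuristic; periodized
        # boundaries keep the transform exactly invertible regardless.
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(values, wavelet_name, mode=_MODE, level=levels)
    return WaveletCoeffs(
        approx=coeffs[0],
        details=coeffs[1:],
        wavelet_name=wavelet_name,
        original_length=n,
    )


def idwt_multilevel(coeffs: WaveletCoeffs) -> np.ndarray:
    """Inverse pyramid transform back to a length-``N`` sample vector."""
    expect = band_sizes(coeffs.original_length, coeffs.levels)
    have = [b.size for b in coeffs.bands()]
    if have != expect:
        raise ValueError(f"band sizes {have} inconsistent with N={coeffs.original_length} (expect {expect})")
    rec = pywt.waverec(
        [coeffs.approx] + list(coeffs.details), coeffs.wavelet_name, mode=_MODE
    )
    return rec[: coeffs.original_length]


def quantize_coeffs(coeffs: WaveletCoeffs, step: float) -> WaveletCoeffs:
    """Uniform scalar quantization: each coefficient becomes ``round(c / step)``."""
    if step <= 0:
        raise ValueError("step must be positive")
    return replace(
        coeffs,
        approx=np.round(coeffs.approx / step),
        details=[np.round(d / step) for d in coeffs.details],
        quant_step=step,
    )


def dequantize_coeffs(coeffs: WaveletCoeffs) -> WaveletCoeffs:
    """Undo :func:`quantize_coeffs` (multiply indices back by the step)."""
    step = coeffs.quant_step
    if step is None:
        raise ValueError("coefficients are not quantized")
    return replace(
        coeffs,
        approx=coeffs.approx * step,
        details=[d * step for d in coeffs.details],
        quant_step=None,
    )
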