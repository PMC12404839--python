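"""Statistical descriptors of (reconstructed) EEG segments.

Five features per scope: histogram entropy (bits), skewness, kurtosis,
variance and mean.  Moments are population moments (divide by ``n``);
kurtosis is the raw fourth standardized moment (Gaussian reference value 3,
leptokurtic > 3), skewness the third.  Entropy is the Shannon entropy of the
normalized amplitude histogram.  Seizure activity raises entropy, kurtosis,
skewness and mean relative to background EEG — the separation the classifier
exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ezweeg.signal_io import Segment
from ezweeg.wavelet import WaveletCoeffs

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "histogram_entropy",
    "kurtosis",
    "skewness",
    "basic_moments",
    "feature_vector",
    "feature_table",
]

FEATURE_NAMES = ("entropy", "skewness", "kurtosis", "variance", "mean")


@dataclass(frozen=True)
class FeatureVector:
    """The five descriptors for one scope (a whole segment or one subband)."""

    entropy: float
    skewness: float
    kurtosis: float
    variance: float
    mean: float
    scope: str = "segment"

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))

    def as_array(self) -> np.ndarray:
        return np.array([self.entropy, self.skewness, self.kurtosis, self.variance, self.mean])


def histogram_entropy(values: np.ndarray, n_bins: int = 256, normalized: bool = True) -> float:
    """Shannon entropy (bits) of the amplitude histogram over uniform bins.

    With ``normalized=False`` the raw-count form ``sum z * log2 z`` is
    returned instead (a size-dependent quantity kept for comparison; the
    normalized form is the default and the one used throughout the pipeline).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    counts, _ = np.histogram(values, bins=n_bins)
    if not normalized:
        z = counts[counts > 0].astype(float)
        return float(np.sum(z * np.log2(z)))
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def basic_moments(values: np.ndarray) -> tuple[float, float, float]:
    """Population mean, variance and standard deviation."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty vector")
    mean = float(values.mean())
    var = float(values.var())  # ddof=0: population moment
    return mean, var, float(np.sqrt(var))


def _central_moments(values: np.ndarray) -> tuple[float, float, float, float]:
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least 2 samples")
    d = values - values.mean()
    m2 = float(np.mean(d**2))
    if m2 == 0:
        raise ValueError("moment ratios undefined for a constant vector")
    return m2, float(np.mean(d**3)), float(np.mean(d**4)), float(values.mean())


def kurtosis(values: np.ndarray) -> float:
    """Fourth standardized moment ``m4 / m2**2`` (3 for a Gaussian)."""
    m2, _, m4, _ = _central_moments(values)
    return m4 / m2**2


def skewness(values: np.ndarray) -> float:
    """Third standardized moment ``m3 / m2**1.5``."""
    m2, m3, _, _ = _central_moments(values)
    return m3 / m2**1.5


def _features_of(values: np.ndarray, scope: str, n_bins: int) -> FeatureVector:
    mean, var, _ = basic_moments(values)
    return FeatureVector(
        entropy=histogram_entropy(values, n_bins),
        skewness=skewness(values),
        kurtosis=kurtosis(values),
        variance=var,
        mean=mean,
        scope=scope,
    )


def feature_vector(
    seg_or_coeffs: Segment | np.ndarray | WaveletCoeffs,
    mode: str = "reconstructed-segment",
    n_bins: int = 256,
) -> list[FeatureVector]:
    """Feature vectors for a segment or a coefficient pyramid.

    ``"reconstructed-segment"`` mode takes a sample vector and yields one
    :class:`FeatureVector`; ``"per-subband"`` mode takes a
    :class:`~ezweeg.wavelet.WaveletCoeffs` pyramid and yields ``L + 1``
    vectors (approximation band, then each detail band coarse to fine), meant
    to be concatenated for the classifier.
    """
    if mode == "reconstructed-segment":
        values = seg_or_coeffs.values if isinstance(seg_or_coeffs, Segment) else np.asarray(seg_or_coeffs)
        return [_features_of(values, "segment", n_bins)]
    if mode == "per-subband":
        if not isinstance(seg_or_coeffs, WaveletCoeffs):
            raise TypeError("per-subband mode requires a WaveletCoeffs pyramid")
        out = [_features_of(seg_or_coeffs.approx, "approx", n_bins)]
        for lvl, d in enumerate(seg_or_coeffs.details):
            out.append(_features_of(d, f"d{seg_or_coeffs.levels - lvl}", n_bins))
        return out
    raise ValueError(f"unknown mode {mode!r}")


def feature_table(
    segments: Sequence[Segment],
    feature_lists: Sequence[Sequence[FeatureVector]],
) -> pd.DataFrame:
    """Flatten per-segment feature vectors into a tidy table (one row per scope)."""
    rows = []
    for seg, fvs in zip(segments, feature_lists):
        for fv in fvs:
            rows.append(
                {
                    "segment_id": seg.segment_index,
                    "channel": seg.channel_index,
                    "scope": fv.scope,
                    "entropy": fv.entropy,
                    "skewness": fv.skewness,
                    "kurtosis": fv.kurtosis,
                    "variance": fv.variance,
                    "mean": fv.mean,
                    "label": seg.label,
                }
            )
    return pd.DataFrame(rows)
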