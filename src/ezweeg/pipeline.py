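"""End-to-end path: preprocess -> DWT -> EZW at a bit budget -> features -> SVM.

The compressed-domain detector reconstructs each segment from its truncated
embedded bitstream and classifies the reconstruction's statistical features.
Defaults: band-pass 1–70 Hz + 50 Hz notch, adaptive median filter, Daubechies-4
DWT at 3 levels, uniform quantization, 4 bits/sample budget, linear SVM.

Histogram equalization (available in :mod:`ezweeg.preprocess`) is deliberately
not part of the default feature path: it is a monotone rank-flattening map, and
applying it before amplitude-moment features would erase the distribution
shape (kurtosis, skewness, entropy) the classifier relies on.  Enable it via
``PipelineConfig.equalize`` for contrast-enhanced export or inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ezweeg import classify, ezw
from ezweeg.features import FeatureVector, feature_vector
from ezweeg.preprocess import FilterSpec, adaptive_median_filter, filter_values, histogram_equalize
from ezweeg.signal_io import Segment
from ezweeg.wavelet import (
    DEFAULT_LEVELS,
    DEFAULT_WAVELET,
    dequantize_coeffs,
    dwt_multilevel,
    idwt_multilevel,
    quantize_coeffs,
)

__all__ = ["PipelineConfig", "preprocess_segment", "compress_segment", "reconstruct_segment",
           "extract_features", "evaluate_loo"]


@dataclass
class PipelineConfig:
    """Tunable knobs of the compressed-domain detection pipeline."""

    sampling_rate_hz: float = 173.0
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    apply_filter: bool = True
    apply_median: bool = True
    amf_window_init: int = 3
    amf_window_max: int = 9
    equalize: bool = False
    he_bins: int = 256
    wavelet_name: str = DEFAULT_WAVELET
    levels: int = DEFAULT_LEVELS
    quant_step: float = 1.0 / 64.0
    bits_per_sample: float | None = 4.0
    feature_mode: str = "reconstructed-segment"
    kernel: str = "linear"
    svm_c: float = 1.0

    def bit_budget(self, n: int) -> int | None:
        if self.bits_per_sample is None:
            return None
        return int(self.bits_per_sample * n)


def preprocess_segment(seg: Segment, cfg: PipelineConfig) -> Segment:
    """Filtering, adaptive median and (optionally) histogram equalization."""
    out = seg
    if cfg.apply_filter:
        out = Segment(
            values=filter_values(out.values, cfg.sampling_rate_hz, cfg.filter_spec),
            channel_index=out.channel_index,
            segment_index=out.segment_index,
            label=out.label,
        )
    if cfg.apply_median:
        out = adaptive_median_filter(out, cfg.amf_window_init, cfg.amf_window_max)
    if cfg.equalize:
        out = histogram_equalize(out, cfg.he_bins, on_constant="identity")
    return out


def compress_segment(seg: Segment, cfg: PipelineConfig) -> ezw.EZWBitstream:
    """Quantized DWT pyramid coded to the configured bit budget."""
    coeffs = quantize_coeffs(
        dwt_multilevel(seg.values, cfg.levels, cfg.wavelet_name), cfg.quant_step
    )
    return ezw.encode(coeffs, max_bits=cfg.bit_budget(seg.n))


def reconstruct_segment(stream: ezw.EZWBitstream) -> np.ndarray:
    """Decode, dequantize and inverse-transform back to a sample vector."""
    return idwt_multilevel(dequantize_coeffs(ezw.decode(stream)))


def extract_features(
    segments: list[Segment], cfg: PipelineConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and label vector for a labelled segment collection.

    Each segment is preprocessed, compressed to the bit budget, reconstructed,
    and reduced to its feature vector(s); per-subband mode concatenates the
    ``L + 1`` subband vectors.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    labels = []
    for seg in segments:
        pre = preprocess_segment(seg, cfg)
        stream = compress_segment(pre, cfg)
        recon = reconstruct_segment(stream)
        if cfg.feature_mode == "per-subband":
            coeffs = dwt_multilevel(recon, cfg.levels, cfg.wavelet_name)
            fvs = feature_vector(coeffs, "per-subband", cfg.he_bins)
        else:
            fvs = feature_vector(recon, "reconstructed-segment", cfg.he_bins)
        rows.append(np.concatenate([fv.as_array() for fv in fvs]))
        labels.append(seg.label)
    return np.vstack(rows), np.asarray(labels)


def evaluate_loo(
    segments: list[Segment], cfg: PipelineConfig | None = None
) -> dict[str, float]:
    """Leave-one-out evaluation of the full pipeline on labelled segments."""
    cfg = cfg or PipelineConfig()
    x, y = extract_features(segments, cfg)
    counts = classify.loo_cv(x, y, kernel=cfg.kernel, c=cfg.svm_c)
    p = classify.precision(counts)
    r = classify.recall(counts)
    return {
        "tp": counts.tp,
        "fp": counts.fp,
        "fn": counts.fn,
        "tn": counts.tn,
        "precision_pct": p,
        "recall_pct": r,
        "f_score_pct": classify.f_score(p, r),
        "accuracy_pct": classify.accuracy(counts),
        "fp_rate_pct": classify.fp_rate(counts),
    }
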