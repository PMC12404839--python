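"""Cluster/differential encoding of similar segments.

Segments drawn as prototype + small noise are grouped by K-means; members are
then coded as zerotree streams of their residual against the cluster
prototype (cluster id in an 8-bit preamble).  The residuals have few
significant coefficients, so the differential total is far below coding each
segment independently at the same quantizer (same distortion).
"""

import numpy as np

from ezweeg.cluster import cluster_segments, differential_decode, differential_encode
from ezweeg.ezw import encode
from ezweeg.signal_io import Segment
from ezweeg.wavelet import dwt_multilevel, quantize_coeffs

rng = np.random.default_rng(0)
prototypes = rng.standard_normal((3, 256)) * 10
segments = [
    Segment(prototypes[i % 3] + 0.05 * rng.standard_normal(256), segment_index=i + 1)
    for i in range(12)
]

model = cluster_segments(segments, n_clusters=3, seed=0)
step = 1.0 / 16
diff_bits, indep_bits = 0, 0
for seg in segments:
    stream = differential_encode(seg, model, quant_step=step)
    diff_bits += stream.total_bits
    indep_bits += encode(quantize_coeffs(dwt_multilevel(seg.values, 3, "db4"), step)).total_bits
    recon = differential_decode(stream, model)
    assert np.abs(recon.values - seg.values).max() < step  # lossless to the quantizer

print(f"12 segments, 3 clusters, quantizer step {step}")
print(f"independent coding : {indep_bits} bits")
print(f"differential coding: {diff_bits} bits  ({100 * diff_bits / indep_bits:.1f}% of independent)")
print("both decode to the same distortion (quantization error only)")
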