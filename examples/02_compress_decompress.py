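"""Progressive zerotree compression of one EEG segment.

Encodes a synthetic segment at several bit budgets and prints the achieved
rate and reconstruction error: the embedded bitstream means every larger
budget strictly refines the smaller one, so RMSE falls as the rate grows,
reaching the quantizer floor in lossless mode.
"""

import numpy as np

from ezweeg.ezw import bits_per_sample, decode, encode
from ezweeg.synth import SynthSpec, generate_background
from ezweeg.wavelet import dequantize_coeffs, dwt_multilevel, idwt_multilevel, quantize_coeffs

spec = SynthSpec(segment_s=10.0)
x = generate_background(spec, seed=42).values
coeffs = quantize_coeffs(dwt_multilevel(x, levels=3, wavelet_name="db4"), step=1.0 / 64)

print(f"segment: {x.size} samples, {spec.segment_s:.0f} s at {spec.sampling_rate_hz:.0f} Hz")
print(f"{'budget (b/s)':>12}{'rate (b/s)':>12}{'RMSE':>10}")
for bps in [0.5, 1, 2, 4, 8, None]:
    stream = encode(coeffs, max_bits=None if bps is None else int(bps * x.size))
    recon = idwt_multilevel(dequantize_coeffs(decode(stream)))
    rmse = np.sqrt(np.mean((recon - x) ** 2))
    label = "lossless" if bps is None else f"{bps:.1f}"
    print(f"{label:>12}{bits_per_sample(stream):>12.2f}{rmse:>10.4f}")
print("\nthe final row's RMSE is pure quantization error (step/2 bound per coefficient)")
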