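"""Compressed-domain seizure detection with leave-one-out evaluation.

Runs the whole pipeline on a small synthetic dataset: band-pass + notch
filtering and adaptive median filtering, zerotree compression at 4 bits per
sample, feature extraction from the reconstructions, and a linear soft-margin
SVM evaluated by leave-one-out cross-validation.  Prints the confusion counts
and the percentage metrics (precision, recall, F score, accuracy, false
positive rate).
"""

from ezweeg.pipeline import PipelineConfig, evaluate_loo
from ezweeg.synth import SynthSpec, generate_dataset

spec = SynthSpec(n_normal=15, n_epileptic=15, segment_s=20.0, seed=7)
segments, _ = generate_dataset(spec)
cfg = PipelineConfig(bits_per_sample=4.0)

metrics = evaluate_loo(segments, cfg)
print(f"{len(segments)} segments of {spec.segment_s:.0f} s, EZW at {cfg.bits_per_sample} bits/sample\n")
print(f"confusion: TP={metrics['tp']} FP={metrics['fp']} FN={metrics['fn']} TN={metrics['tn']}")
for key in ("precision_pct", "recall_pct", "f_score_pct", "accuracy_pct", "fp_rate_pct"):
    print(f"{key:<14}: {metrics[key]:6.2f}%")
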