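"""Published benchmark confusion counts for seizure-detection evaluation.

Fifteen dataset-level confusion-count rows (TP, FP, FN, TN) from a published
EEG seizure-detection evaluation, used to exercise the percentage metrics on
realistic epoch counts.  The counts are inputs; precision, recall and F score
are always recomputed from them, never stored.
"""

from __future__ import annotations

from ezweeg.classify import ConfusionCounts

__all__ = ["BENCHMARK_CONFUSION_ROWS"]

#: (TP, FP, FN, TN) per dataset row
BENCHMARK_CONFUSION_ROWS: list[ConfusionCounts] = [
    ConfusionCounts(tp, fp, fn, tn)
    for tp, fp, fn, tn in [
        (491, 2, 1, 35),
        (425, 4, 2, 30),
        (446, 5, 3, 36),
        (482, 3, 1, 52),
        (391, 0, 4, 36),
        (374, 4, 2, 37),
        (421, 0, 1, 39),
        (312, 2, 3, 34),
        (415, 2, 2, 42),
        (399, 2, 2, 52),
        (487, 4, 2, 64),
        (357, 0, 4, 38),
        (405, 3, 0, 45),
        (392, 3, 2, 50),
        (465, 5, 0, 46),
    ]
]
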