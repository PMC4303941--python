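"""Simulate the six-volunteer binary time-course cohort with ground truth.

Generates ~2000 presence/absence protein profiles over weeks -4..18: ten
planted wave-like co-expression modules (phases staggered from the start
to after the end of isolation, cosine and single-peak shapes) plus
invariantly present, invariantly absent and single-spiked background.
"""

from collections import Counter

from common import config
from somportrait.pipeline import run_stage

cfg = config()
paths = run_stage(cfg, "simulate")

from somportrait.cohort import read_ground_truth  # noqa: E402

labels = Counter(read_ground_truth(f"{cfg.out_dir}/ground_truth.tsv").values())
n = sum(labels.values())
background = labels["invariant-high"] + labels["invariant-low"] + labels["spiked"]
print(f"cohort written: {len(paths) - 1} volunteer matrices, {n} proteins")
print(f"planted modules: {sorted(k for k in labels if k.startswith('M'))}")
print(
    f"background: {labels['invariant-high']} invariant-high, "
    f"{labels['invariant-low']} invariant-low, {labels['spiked']} single-spiked "
    f"({100 * background / n:.1f}% outside modules)"
)
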