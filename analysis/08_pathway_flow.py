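"""Pathway signal flow over toy pathways and matching to spot profiles.

Each planted module feeds a three-node activation chain; the per-week
fold changes of its member proteins propagate to the sink, and the sink's
PSF time profile is matched to the spot profiles by Pearson correlation.
"""

import pandas as pd

from common import config
from somportrait.pipeline import run_stage

cfg = config()
run_stage(cfg, "psf")

matches = pd.read_csv(f"{cfg.out_dir}/psf_matches.tsv", sep="\t")
best = matches[matches["best"]].sort_values("sink")
print("best spot match per pathway sink:")
print(best[["sink", "spot", "r"]].to_string(index=False))
print(f"median best-match correlation: {best['r'].median():.2f}")
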