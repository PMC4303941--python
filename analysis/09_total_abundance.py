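"""Total-abundance dynamics from the absolute-value map.

The variance of the meta-feature landscape per week tracks the overall
abundance amplitude; local maxima of that profile mark the abundance
peaks (the study reports 3-4, spaced ~5 weeks apart).
"""

import pandas as pd

from common import config
from somportrait.pipeline import run_stage

cfg = config()
run_stage(cfg, "total_abundance")

df = pd.read_csv(f"{cfg.out_dir}/total_abundance.tsv", sep="\t")
peaks = df[df.is_peak]["week"].tolist()
print(f"variance profile over {len(df)} weeks; detected peaks at weeks {peaks}")
if len(peaks) > 1:
    gaps = [b - a for a, b in zip(peaks, peaks[1:])]
    print(f"peak spacing: {gaps} weeks")
early = df[df.week <= 6]["variance"].mean()
late = df[df.week >= 12]["variance"].mean()
print(f"mean variance early {early:.4f} vs late {late:.4f}")
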