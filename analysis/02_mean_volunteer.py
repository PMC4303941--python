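"""Assemble the mean-volunteer matrix and centralize the profiles.

Each cell is the fraction of volunteers detecting the protein that week;
centralization subtracts every protein's own mean so profiles read as
over-/under-presence (dE).
"""

import pandas as pd

from common import config
from somportrait.pipeline import run_stage

cfg = config()
run_stage(cfg, "mean_volunteer")

mean = pd.read_csv(f"{cfg.out_dir}/mean_volunteer.tsv", sep="\t", index_col=0)
diff = pd.read_csv(f"{cfg.out_dir}/mean_volunteer_centralized.tsv", sep="\t", index_col=0)
print(f"mean-volunteer matrix: {mean.shape[0]} proteins x {mean.shape[1]} weeks")
print(f"detection fractions span [{mean.values.min():.2f}, {mean.values.max():.2f}]")
print(f"centralized row-mean magnitude: {abs(diff.values.mean(axis=1)).max():.1e}")
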