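"""Spot-spot wTO networks and beta co-expression significance.

The weighted topological overlap connects spots whose meta-features
correlate directly or via mediating nodes (separate positive and negative
channels); the beta test scores each spot's internal coherence against a
map-resampling permutation null with BH adjustment.
"""

import pandas as pd

from common import config
from somportrait.pipeline import run_stage

cfg = config()
run_stage(cfg, "networks")

edges = pd.read_csv(f"{cfg.out_dir}/wto_edges.tsv", sep="\t")
beta = pd.read_csv(f"{cfg.out_dir}/beta_results.tsv", sep="\t")
for ch, grp in edges.groupby("channel"):
    top = grp.nlargest(3, "score")
    pairs = ", ".join(f"{r.spot_i}-{r.spot_j} ({r.score:.2f})" for r in top.itertuples())
    print(f"{ch} channel: {len(grp)} edges; strongest: {pairs}")
sig = beta[beta.p_adj < 0.05]
print(f"beta test: {len(sig)}/{len(beta)} spots significantly coherent (BH p < 0.05)")
print(beta.nlargest(5, "beta")[["spot", "beta", "p", "p_adj", "m"]].to_string(index=False))
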