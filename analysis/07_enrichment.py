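"""Gene-set enrichment of the spot modules.

With no external GMT configured, the planted ground-truth labels act as
the gene-set collection, so enrichment should rediscover which module
feeds which spot: Fisher hypergeometric p plus the GSZ overexpression
score, BH-adjusted, rendered as a phase-ordered heat map.
"""

import pandas as pd

from common import config
from somportrait.pipeline import run_stage

cfg = config()
run_stage(cfg, "enrichment")

res = pd.read_csv(f"{cfg.out_dir}/enrichment.tsv", sep="\t")
hits = res[(res.p_adj < 0.01) & (res.overlap > 0)]
print(f"{len(hits)} significant spot-set associations (BH p < 0.01)")
best = hits.loc[hits.groupby("spot")["p_adj"].idxmin()]
print(best[["spot", "set", "overlap", "n_set", "p_adj", "gsz"]].to_string(index=False))
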