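"""Project weekly samples into similarity space and segment the trajectory.

Both a second-level SOM and ICA place the 23 weekly expression states in
2-D; k-means (k = 3) on the coordinates is compared against the reference
early/intermediate/late phases by adjusted Rand index.
"""

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from common import config
from somportrait.pipeline import run_stage

cfg = config()
run_stage(cfg, "trajectories")

for method in ("som2", "ica"):
    df = pd.read_csv(f"{cfg.out_dir}/trajectory_{method}.tsv", sep="\t")
    ari = adjusted_rand_score(df["reference_phase"], df["segment"])
    mism = df[df["segment"] != df["reference_phase"]]["week"].tolist()
    print(f"{method}: segmentation ARI vs reference phases = {ari:.3f}")
    if mism:
        print(f"  boundary/misassigned weeks: {mism}")
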