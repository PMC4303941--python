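"""Segment the map into over-/under-expression spot modules.

Per week, the top and bottom 2-percentile of meta-feature values are
selected; the per-week selections are unioned and split into grid-connected
spots. Each spot's mean dE profile gives its phase (argmax week) and its
reference-phase class.
"""

import pandas as pd

from common import config
from somportrait.io import StudyDesign
from somportrait.pipeline import run_stage

cfg = config()
run_stage(cfg, "spots")

spots = pd.read_csv(f"{cfg.out_dir}/spots.tsv", sep="\t")
design = StudyDesign.default()
spots["phase_class"] = spots["phase_week"].map(design.phase_of)
over = spots[spots.polarity == "over"]
print(f"{len(over)} over-expression and {len(spots) - len(over)} under-expression spots")
print(over[["spot", "n_nodes", "n_members", "phase_week", "phase_class"]].to_string(index=False))
counts = over.groupby("phase_class")["n_members"].sum()
print("proteins captured per phase:", counts.to_dict())
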