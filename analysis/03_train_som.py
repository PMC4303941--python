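"""Train the 40x40 SOM and render the weekly abundance portraits.

Two maps are trained: one on centralized (dE) profiles, which feeds spots,
trajectories and networks, and one on absolute detection fractions for the
total-abundance analysis. Portraits (one PNG per week) visualize the 1600
meta-feature values as a red/blue landscape.
"""

from common import config
from somportrait.pipeline import run_stage
from somportrait.som import load_model, population_map

cfg = config()
run_stage(cfg, "som")
paths = run_stage(cfg, "portraits")

model = load_model(f"{cfg.out_dir}/som_model.npz")
pop = population_map(model)
print(f"map: {model.meta.shape[0]} meta-features x {model.meta.shape[1]} weeks")
print(
    f"quantization error {model.quantization_error_initial:.4f} -> "
    f"{model.quantization_error:.4f}"
)
print(f"occupied nodes: {(pop > 0).sum()} / {pop.size}; busiest node holds {pop.max()} proteins")
print(f"portrait gallery: {len(paths)} images under {cfg.out_dir}/portraits/")
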