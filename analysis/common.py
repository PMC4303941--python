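"""Shared run configuration for the numbered analysis drivers.

All drivers write into the same run directory so each step can pick up
the cached artifacts of its predecessors (run them in order).
"""

from somportrait.pipeline import PipelineConfig

RUN_DIR = "results/run"
SEED = 1


def config() -> PipelineConfig:
    return PipelineConfig(out_dir=RUN_DIR, seed=SEED)
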