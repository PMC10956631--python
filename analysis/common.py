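"""Shared configuration for the numbered analysis drivers.

One study-scale synthetic dataset: 200 placental samples, 2,000 EPIC-like
CpGs and 100 genes on a 20 Mb synthetic autosome, 15 planted cis eQTHM
effects and 2 planted 5-CpG DHMRs, scanned with 1,000 permutations. Every
driver re-derives the (deterministic) upstream stages it needs, so each can
be run on its own; artifacts land in results/analysis/.
"""

from eqthm.config import PipelineConfig, SynthConfig

OUT_DIR = "results/analysis"


def analysis_config() -> PipelineConfig:
    return PipelineConfig(
        synth=SynthConfig(seed=20240320),
        n_perm=1000,
        out_dir=OUT_DIR,
    )


def run_through(stage: str):
    """Run the pipeline up to and including ``stage``; returns the state."""
    from eqthm.pipeline import run_pipeline

    order = ["simulate", "preprocess", "annotate", "scan", "dhmr", "enrich"]
    cfg = analysis_config()
    wanted = order[:order.index(stage) + 1]
    for name in order:
        setattr(cfg, f"run_{name}", name in wanted)
    return run_pipeline(cfg)
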