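"""Shared configuration for the numbered analysis drivers.

All drivers operate on one seeded study under results/study/ and are
individually re-runnable: prerequisites are executed on demand and cached
as pipeline stage blocks.
"""

import json
import os

from netdissect import pipeline, synth

ROOT = os.path.normpath(os.path.join(os.path.dirname(__file__), ".."))
OUTDIR = os.path.join(ROOT, "results", "study")
SEED = 1


def config() -> pipeline.PipelineConfig:
    return pipeline.PipelineConfig(
        outdir=OUTDIR, seed=SEED, synth=synth.SynthConfig(seed=SEED)
    )


def ensure(cfg: pipeline.PipelineConfig, upto: str) -> dict:
    """Run pipeline stages up to and including ``upto``; reuse cached blocks."""
    blocks = {}
    for stage in pipeline.STAGES:
        bpath = os.path.join(cfg.outdir, "stages", f"{stage}.json")
        if os.path.exists(bpath):
            with open(bpath) as fh:
                blocks[stage] = json.load(fh)
        else:
            blocks[stage] = pipeline._STAGE_FUNCS[stage](cfg)
            pipeline._write_json(blocks[stage], bpath)
        if stage == upto:
            break
    return blocks


def show(title: str, block: dict) -> None:
    print(f"== {title} ==")
    print(json.dumps(block, indent=1, sort_keys=True))
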