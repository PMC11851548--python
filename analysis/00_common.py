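"""Shared plumbing for the analysis drivers.

All drivers work off one deterministic demo mapping experiment (seed 1,
default study conditions: 5 x 5 Mb chromosomes, 500 EMS variants, one
3:1-segregating F3 family of 200 plants, two 30-plant bulks at 30x).  Large
artifacts live under scratch/, small result tables under results/.
"""

from __future__ import annotations

from pathlib import Path

from bsamap import pipeline

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
DEMO_DIR = SCRATCH / "demo_run"
DEMO_SEED = 1


def demo_run(plots: bool = False) -> Path:
    """Run (or reuse) the deterministic demo pipeline; returns its directory."""
    RESULTS.mkdir(exist_ok=True)
    if not (DEMO_DIR / "report.md").exists():
        cfg = pipeline.RunConfig(seed=DEMO_SEED)
        pipeline.run_pipeline(cfg, DEMO_DIR, plots=plots)
    return DEMO_DIR
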