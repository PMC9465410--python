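"""Shared configuration for the numbered analysis drivers.

All drivers operate on one pipeline run under results/pipeline (files are the
interface between stages, so later drivers can inspect or re-run any stage).
Import as a module:  from analysis (run scripts from the repo root).
"""

from pathlib import Path

from netpharm.pipeline import RunConfig
from netpharm.synthetic_data import SimConfig

REPO = Path(__file__).resolve().parent.parent
RESULTS = REPO / "results"
PIPELINE_DIR = RESULTS / "pipeline"

SEED = 11


def run_config(stages) -> RunConfig:
    return RunConfig(
        outdir=str(PIPELINE_DIR),
        seed=SEED,
        stages=tuple(stages),
        sim=SimConfig(seed=SEED),
    )


def ensure_simulated() -> None:
    """Drivers 02-05 need the simulated inputs; generate them if missing."""
    from netpharm.pipeline import run_pipeline

    if not (PIPELINE_DIR / "network.tsv").exists():
        run_pipeline(run_config(("simulate",)))
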