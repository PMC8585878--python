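"""Shared plumbing for the numbered analysis drivers.

Every driver works off the same deterministic full-pipeline run (seed 1) so
the stage tables they present are mutually consistent; the run itself takes
a few seconds and is recomputed per script to keep each driver standalone.
"""

from __future__ import annotations

import warnings
from pathlib import Path

from gazeforge.pipeline import RunConfig, run_pipeline

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def default_bundle():
    cfg = RunConfig(seed=SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cfg, run_pipeline(cfg)


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
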