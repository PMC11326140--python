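"""Deterministic seed derivation.

One global seed is expanded into independent per-stage streams through
``numpy.random.SeedSequence`` with a fixed spawn key per stage name, so no
stage's draws depend on how many draws another stage made.
"""

from __future__ import annotations

import numpy as np

#: Fixed stage order; the index is the spawn key.
STAGES = (
    "simulate",
    "preprocess",
    "extract",
    "synthesize",
    "compare",
    "validate",
    "null-tps",
    "null-treking",
)


def stage_rng(global_seed: int, stage: str, iteration: int = 0) -> np.random.Generator:
    """Generator for ``stage`` (optionally a numbered sub-iteration)."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    key = (STAGES.index(stage), iteration)
    return np.random.default_rng(np.random.SeedSequence(global_seed, spawn_key=key))


def stage_seed(global_seed: int, stage: str, iteration: int = 0) -> int:
    """A plain integer seed (< 2**31) derived for ``stage``."""
    return int(stage_rng(global_seed, stage, iteration).integers(0, 2**31))
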