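"""Shared fixtures: small simulated experiments generated at test time."""

from __future__ import annotations

import logging
from types import SimpleNamespace

import numpy as np
import pytest

from mazedecode import default_maze
from mazedecode.pipeline import (
    ExperimentConfig,
    decode_experiment,
    rank_experiment,
    simulate_behavior,
    synthesize_and_prepare,
)

logging.getLogger("mazedecode").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def maze():
    return default_maze()


@pytest.fixture(scope="session")
def behavior_small():
    """Six simulated trials at reduced renderer resolution (behavior only)."""
    cfg = ExperimentConfig(
        seed=7, n_sessions=1, trials_per_session=6, resolution=(48, 64), rois=("M1",)
    )
    return SimpleNamespace(config=cfg, data=simulate_behavior(cfg))


@pytest.fixture(scope="session")
def experiment():
    """The study-scale synthetic experiment shared by pipeline-level tests:
    2 sessions x 10 trials, a visual ROI, a motor ROI and the white-matter
    control, decoded for all six sources at high snr."""
    cfg = ExperimentConfig(
        seed=1234,
        n_sessions=2,
        trials_per_session=10,
        resolution=(48, 64),
        snr=8.0,
        rois=("V1", "M1", "WM"),
    )
    behavior = simulate_behavior(cfg)
    aligned = synthesize_and_prepare(cfg, behavior)
    decoded = decode_experiment(cfg, aligned)
    library, combos = rank_experiment(cfg, behavior, decoded)
    return SimpleNamespace(
        config=cfg,
        behavior=behavior,
        aligned=aligned,
        decoded=decoded,
        library=library,
        combos=combos,
    )
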