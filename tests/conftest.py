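"""Shared fixtures.

The full-scale pipeline run (24 subjects, both drug arms, all four PCAs)
is expensive, so it is computed once per session and shared by the
parameter-recovery, reconstitution, matching and regression tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gonogopca.data import AverageSet
from gonogopca.montage import default_montage
from gonogopca.pipeline import PipelineConfig, run_pipeline
from gonogopca.simulate import GeneratorConfig
from gonogopca.templates import make_default_templates

SUITE_SEED = 1


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def templates(montage):
    return make_default_templates(montage)


@pytest.fixture
def tiny_config():
    """Small, fast generator configuration for unit tests."""
    return GeneratorConfig(n_subjects=3, tones_per_block=20, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def default_run():
    """Full default crossover run: study-scale simulation, preprocessing,
    four PCAs, matching and the contrast batteries (no planted drug
    effect)."""
    cfg = PipelineConfig(seed=SUITE_SEED)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def synthetic_averages(montage):
    """Random 26-subject AverageSet with the study's geometry (19 channels,
    218 time points at 256 Hz) for structural checks, bypassing the
    simulator."""
    rng = np.random.default_rng(0)
    n_subj, n_blocks = 26, 2
    times = -0.1 + np.arange(218) * 2 / 512.0
    rows, data = [], []
    for s in range(n_subj):
        for d in ("placebo", "caffeine"):
            for b in range(n_blocks):
                for c in ("go", "nogo"):
                    rows.append((s, d, b, c, 70, 75))
                    data.append(rng.normal(0, 1, size=(19, 218)))
    meta = pd.DataFrame(rows, columns=["subject", "drug", "block",
                                       "condition", "n_accepted", "n_presented"])
    return AverageSet(
        data=np.stack(data), channels=list(montage.scalp_channels),
        times=times, sfreq=256.0, meta=meta, montage=montage)
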