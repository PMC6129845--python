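"""Shared fixtures: one small synthetic recording for unit tests and one
full-scale five-slice run for the recovery/acceptance checks (both built
once per session)."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from prebotseq.benchmark import score_slice
from prebotseq.pipeline import PipelineConfig, SliceSpec, run_slice
from prebotseq.synthetic_data import (
    SynthConfig,
    default_paper_like_config,
    generate_recording,
)

SMALL_OVERRIDES = {
    "n_cells_per_type": {
        "R-Ex": 4, "R-Gly": 2, "Irr-Ex": 4, "Irr-Gly": 2,
        "Irr-Cotrans": 2, "NonRhythmic": 2,
    },
    "n_bursts": 40,
    "frame_shape": (64, 64),
    "burst_interval_s": (4.0, 0.5),
    "sigh_every_n": 10.0,
}


def small_config(seed: int = 1) -> SynthConfig:
    return dataclasses.replace(default_paper_like_config(seed=seed),
                               **SMALL_OVERRIDES)


@pytest.fixture(scope="session")
def small_recording():
    """(movie, stack, lfp, truth) for a 14-cell, 40-burst, 64x64 recording."""
    return generate_recording(small_config(seed=1))


@pytest.fixture(scope="session")
def small_run():
    """Full single-slice pipeline products on the small recording."""
    cfg = PipelineConfig(
        slices=[SliceSpec(label="s1", seed=1)], synth=SMALL_OVERRIDES,
        make_figures=False,
    )
    return run_slice(cfg, cfg.slices[0])


@pytest.fixture(scope="session")
def default_results():
    """Five full-scale slices (default generator, seeds 1-5), analyzed."""
    results = []
    for seed in range(1, 6):
        cfg = PipelineConfig(
            slices=[SliceSpec(label=str(seed), seed=seed)], make_figures=False
        )
        results.append(run_slice(cfg, cfg.slices[0]))
    return results


@pytest.fixture(scope="session")
def default_scores(default_results):
    return [score_slice(r) for r in default_results]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
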