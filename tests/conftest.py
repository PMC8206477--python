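"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from brainnets.io_core import StudyConfig, compute_mask
from brainnets.synthetic import EffectSpec, SourceSpec, generate_cohort

SMALL_GRID = (16, 18, 16)
MID_GRID = (24, 28, 24)


@pytest.fixture(scope="session")
def small_spec() -> SourceSpec:
    return SourceSpec(K=3, grid_shape=SMALL_GRID)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """3 case + 3 control, K = 3 networks, modest noise; in-memory only."""
    effect = EffectSpec(K=3, noise_sigma=0.1)
    table, truth, series = generate_cohort(
        3, 3, small_spec, effect, seed=11, out_dir=".", write_files=False,
        T=100)
    return table, truth, series


@pytest.fixture(scope="session")
def noiseless_cohort(small_spec):
    """2 + 2 subjects with zero noise: exact bilinear data."""
    effect = EffectSpec(K=3, noise_sigma=0.0)
    table, truth, series = generate_cohort(
        2, 2, small_spec, effect, seed=5, out_dir=".", write_files=False,
        T=80)
    return table, truth, series


@pytest.fixture(scope="session")
def small_mask(small_cohort):
    _, _, series = small_cohort
    return compute_mask(series)
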