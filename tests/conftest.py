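"""Shared fixtures: one default simulated dataset reused across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from allofiber import SimConfig, simulate_dataset
from allofiber.bias import call_bias
from allofiber.cli import run_temporal
from allofiber.temporal import FuzzyParams


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition simulated dataset with planted truth (seed 1)."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_bias_calls(default_sim):
    dataset, _ = default_sim
    return call_bias(dataset.counts, dataset.sheet, dataset.pairs)


@pytest.fixture(scope="session")
def default_temporal(default_sim):
    dataset, _ = default_sim
    return run_temporal(dataset, FuzzyParams(seed=1))


@pytest.fixture(scope="session")
def null_sim():
    """Zero-effect simulation: 2000 pairs, no planted bias or shifts."""
    config = SimConfig(
        seed=1, n_pairs=2000, frac_biased=0.0, frac_postponed=0.0,
        n_modules=0, module_size=0,
    )
    return simulate_dataset(config)


@pytest.fixture()
def tiny_counts_tsv(tmp_path):
    path = tmp_path / "counts.tsv"
    path.write_text(
        "gene_id\ts1\ts2\ngA\t5\t8\ngB\t0\t3\n", encoding="utf-8"
    )
    return path
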