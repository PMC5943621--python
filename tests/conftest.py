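"""Shared fixtures: small simulated communities and the full toy study.

The toy study (15+15 samples, 50 kb genomes, ~24x minimum depth, k=31) is
expensive, so it is built once per session and shared by every test that
needs the full-design conditions."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kmersig.kmers import count_kmers
from kmersig.matrix import build_matrix, filter_sparse
from kmersig.simulate import SMALL, TOY, SimConfig, simulate_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

TOY_SEED = 1234
SMALL_SEED = 4321


def _count_dataset(cfg: SimConfig, seed: int, keep_reads: bool = False):
    truth, readsets, sheet = simulate_dataset(cfg, seed=seed)
    vectors = []
    kept_reads = {}
    for rs in readsets:
        vectors.append(count_kmers(rs.reads, cfg.k, min_count=2, sample_id=rs.sample_id))
        if keep_reads:
            kept_reads[rs.sample_id] = rs
        rs.reads = []  # free ~1 GB of read strings once counted
    return SimpleNamespace(
        cfg=cfg, truth=truth, sheet=sheet, vectors=vectors, readsets=kept_reads
    )


@pytest.fixture(scope="session")
def toy():
    """Full toy study design, counted and matrix-built once per session."""
    data = _count_dataset(TOY, TOY_SEED)
    F = build_matrix(data.vectors, data.sheet)
    data.F = filter_sparse(F, 0.8)
    data.n_rows_unfiltered = F.n_features
    return data


@pytest.fixture(scope="session")
def small():
    """Scaled-down community (3 kb genomes, 10+10 samples, ~20x depth)."""
    return _count_dataset(SMALL, SMALL_SEED, keep_reads=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
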