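"""Shared fixtures: small genotype fixtures and session-scoped null simulations.

The no-migration null simulations are the most expensive shared resource
(used by threshold calibration, the exceedance check and scenario recovery),
so they are computed once per session with fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

import craterscan as cs
from craterscan.genotype_io import MISSING, GenotypeMatrix, PopulationMap, VariantSite

N_NULL_WINDOWS = 1000
WINDOW_BP = 50_000


def random_matrix(rng: np.random.Generator, n_sites: int = 200, pops: int = 4,
                  diploids_per_pop: int = 3, missing_rate: float = 0.1,
                  chrom: str = "chr1") -> tuple[GenotypeMatrix, PopulationMap]:
    """Random biallelic genotype fixture with missing calls."""
    samples = [f"p{p}_s{i}" for p in range(pops) for i in range(diploids_per_pop)]
    positions = np.sort(rng.choice(np.arange(1, 40_000), size=n_sites, replace=False))
    calls = rng.integers(0, 3, size=(n_sites, len(samples))).astype(np.int8)
    mask = rng.random(calls.shape) < missing_rate
    calls[mask] = MISSING
    sites = [VariantSite(chrom, int(p), "A", "T") for p in positions]
    popmap = PopulationMap({s: f"pop{p}" for p in range(pops)
                            for s in samples[p * diploids_per_pop:(p + 1) * diploids_per_pop]})
    return GenotypeMatrix(sites, samples, calls), popmap


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def base_model() -> cs.DemographicModel:
    return cs.default_radiation_model()


@pytest.fixture(scope="session")
def quartet_mm() -> cs.QuartetConfig:
    return cs.QuartetConfig("lake_A1", "lake_A2", "riverine_MM", "outgroup", "MM")


@pytest.fixture(scope="session")
def quartet_cr() -> cs.QuartetConfig:
    return cs.QuartetConfig("lake_A1", "lake_A2", "riverine_CR", "outgroup", "CR")


@pytest.fixture(scope="session")
def null_fd_mm(base_model, quartet_mm) -> np.ndarray:
    """Defined fd values from 1000 no-migration windows (MM donor)."""
    rng = np.random.default_rng(101)
    return cs.null_fd_values(base_model, quartet_mm, N_NULL_WINDOWS, rng,
                             window_bp=WINDOW_BP)


@pytest.fixture(scope="session")
def null_fd_cr(base_model, quartet_cr) -> np.ndarray:
    """Defined fd values from 1000 no-migration windows (CR donor)."""
    rng = np.random.default_rng(102)
    return cs.null_fd_values(base_model, quartet_cr, N_NULL_WINDOWS, rng,
                             window_bp=WINDOW_BP)


@pytest.fixture(scope="session")
def null_fd_fresh(base_model, quartet_mm) -> np.ndarray:
    """An independent second draw of 1000 no-migration windows (MM donor)."""
    rng = np.random.default_rng(103)
    return cs.null_fd_values(base_model, quartet_mm, N_NULL_WINDOWS, rng,
                             window_bp=WINDOW_BP)
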