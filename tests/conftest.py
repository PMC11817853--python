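import logging

import numpy as np
import pandas as pd
import pytest

from invscan.synthetic_data import (
    SimConfig,
    apply_ascertainment,
    default_metadata,
    simulate_cohort,
)
from invscan.variant_io import GenotypeMatrix

logging.getLogger("invscan").setLevel(logging.ERROR)


def make_matrix(dosage, chrom="chr1", positions=None, samples=None) -> GenotypeMatrix:
    """Small GenotypeMatrix from a literal dosage array (one chromosome)."""
    dosage = np.asarray(dosage, dtype=float)
    n_samples, n_sites = dosage.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "T"}
    )
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(samples=samples, sites=sites, dosage=dosage)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort with ascertainment applied."""
    cfg = SimConfig(seed=1)
    matrix, truth = simulate_cohort(cfg)
    metadata = default_metadata(cfg, matrix)
    observed = apply_ascertainment(matrix, cfg, metadata)
    return cfg, matrix, observed, metadata, truth


@pytest.fixture(scope="session")
def small_structured_cohort():
    """A fast 3-lineage cohort without ascertainment for PCA/FST checks."""
    cfg = SimConfig(
        n_per_lineage={"IND": 20, "SEA": 20, "AUSNG": 20},
        chromosomes=[("chr1", 10_000_000)],
        n_background_snps=800,
        inversions=[],
        seed=7,
    )
    matrix, truth = simulate_cohort(cfg)
    return cfg, matrix, truth
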