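"""Shared fixtures: small simulated datasets built fresh at test time."""

from __future__ import annotations

import numpy as np
import pytest

from interscan.scan import ScanConfig
from interscan.simulate import concat_snps, simulate_genotypes, simulate_phenotypes


def build_dataset(n: int, genome_mafs, rep_mafs, seed: int):
    """Genome + repeating SNPs over the same subjects, plus nothing else."""
    genome = simulate_genotypes(n, np.asarray(genome_mafs, dtype=float), seed=seed)
    repeating = simulate_genotypes(n, np.asarray(rep_mafs, dtype=float), seed=seed + 1, repeating=True)
    return concat_snps(genome, repeating), repeating.snp_ids


@pytest.fixture(scope="session")
def small_dataset():
    """500 subjects, 200 genome SNPs (MAF 0.05-0.5), one repeating SNP at 0.25."""
    mafs = np.linspace(0.05, 0.5, 200)
    merged, rep_ids = build_dataset(500, mafs, [0.25], seed=11)
    phenos = simulate_phenotypes(500, 3, seed=13)
    return merged, rep_ids, phenos


@pytest.fixture()
def ols_config():
    return ScanConfig(estimator="OLS", maf_threshold=0.05, min_cell_count=0)
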