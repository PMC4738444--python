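"""Simulate a null dataset: HWE genotypes plus effect-free phenotypes.

Builds a small cohort (500 subjects, 1,000 genome SNPs, 3 repeating SNPs,
3 phenotypes) with no SNP effects, no LD and no substructure, and checks that
the realized genotype class frequencies match their Hardy-Weinberg targets.
"""

import numpy as np

from interscan import (
    MafSpectrum,
    concat_snps,
    expand_maf_spectrum,
    hwe_genotype_freqs,
    simulate_genotypes,
    simulate_phenotypes,
)

n = 500
genome_mafs = expand_maf_spectrum(MafSpectrum.grid(0.05, 0.5, 0.01), 0, seed=0)
genome_mafs = np.tile(genome_mafs, 22)[:1000]
genome = simulate_genotypes(n, genome_mafs, seed=1)
repeating = simulate_genotypes(n, [0.1, 0.25, 0.4], seed=2, repeating=True)
dataset = concat_snps(genome, repeating)
phenos = simulate_phenotypes(n, 3, seed=3)

print(f"dataset: {dataset.n_subjects} subjects x {dataset.n_snps} SNPs "
      f"({int(dataset.repeating_flags.sum())} repeating)")
for rep_id, maf in zip(repeating.snp_ids, repeating.snp_maf):
    x = dataset.column(rep_id)
    observed = np.bincount(x, minlength=3) / n
    expected = hwe_genotype_freqs(maf)
    print(f"{rep_id} (MAF {maf}): observed class freqs {np.round(observed, 3)}, "
          f"HWE expectation {np.round(expected, 3)}")
# The observed genotype-class proportions scatter around the HWE expectation
# with binomial noise ~ sqrt(f(1-f)/n); nothing else is built into the data.
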