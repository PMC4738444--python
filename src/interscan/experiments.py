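"""Reproducible null-simulation experiments at reduced scale.

Each function runs a complete simulate-scan-summarise experiment that
exhibits one documented behaviour of the interaction-term inflation factor
(lambda_3) under the null hypothesis:

* its spread narrows as sample size grows,
* its spread narrows as the repeating SNP's MAF grows,
* HC3 standard errors narrow its range relative to OLS,
* HC3 without a minimum cell count creates P-value outliers that OLS does not,
* injected heteroskedasticity moves its median in a predictable direction,
* percentiles from the empirical-null comparison are calibrated.

Scales are reduced relative to a full study (genomes of a few thousand SNPs
rather than tens or hundreds of thousands; five to ten phenotypes rather than
nine to one hundred) — lambda is a per-scan median, so its value stabilises
quickly with genome size, while its across-scan spread is driven by the number
of scans and the sample size, both of which are kept in the regime where the
documented patterns are visible.  All randomness derives from the single
``seed`` argument.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .diagnostics import simulate_variance_structured_phenotypes
from .empirical_null import build_null_distribution, compare_lambda
from .scan import ScanConfig, run_study
from .simulate import (
    MafSpectrum,
    concat_snps,
    expand_maf_spectrum,
    simulate_genotypes,
    simulate_phenotypes,
)

__all__ = [
    "null_lambda_study",
    "lambda_spread_vs_sample_size",
    "lambda_spread_vs_maf",
    "hc3_vs_ols_lambda_range",
    "sparse_cell_outliers",
    "heteroskedasticity_direction",
    "compare_lambda_calibration",
    "study_cardinality",
]

#: Default repeating-SNP MAF grid for reduced-scale studies: 0.05-0.5 step 0.05.
REP_GRID = MafSpectrum.grid(0.05, 0.5, 0.05)
#: Default genome spectrum: the common-variant grid 0.05-0.5 step 0.01.
GENOME_SPECTRUM = MafSpectrum.grid(0.05, 0.5, 0.01)


def null_lambda_study(
    n: int,
    seed: int,
    genome_size: int = 2000,
    n_phenotypes: int = 5,
    config: ScanConfig | None = None,
    rep_grid: MafSpectrum = REP_GRID,
    genome_spectrum: MafSpectrum = GENOME_SPECTRUM,
):
    """One matched null study; returns its NullLambdaDistribution."""
    if config is None:
        config = ScanConfig(estimator="OLS", maf_threshold=0.05, min_cell_count=0)
    return build_null_distribution(
        n=n,
        genome_size=genome_size,
        maf_spectrum=genome_spectrum,
        repeating_grid=rep_grid,
        n_phenotypes=n_phenotypes,
        config=config,
        seed=seed,
    )


def lambda_spread_vs_sample_size(seed: int, n_small: int = 1053, n_large: int = 5000,
                                 genome_size: int = 2000, n_phenotypes: int = 5) -> dict:
    """SD of lambda_3 across scans at a small versus a large sample size.

    The across-scan spread of the interaction-term lambda narrows as the
    sample size grows, because test statistics approach their asymptotic
    distribution and within-scan collinearity of the product terms shrinks.
    """
    small = null_lambda_study(n_small, seed, genome_size, n_phenotypes)
    large = null_lambda_study(n_large, seed + 1, genome_size, n_phenotypes)
    return {
        "sd_lambda_small_n": float(np.std(small.lambda_values, ddof=1)),
        "sd_lambda_large_n": float(np.std(large.lambda_values, ddof=1)),
        "n_small": n_small,
        "n_large": n_large,
        "n_scans": len(small.lambda_values),
        "small_study": small,
        "large_study": large,
    }


def lambda_spread_vs_maf(seed: int, n: int = 1053, genome_size: int = 2000,
                         n_phenotypes: int = 5, low_cut: float = 0.15,
                         high_cut: float = 0.35, study=None) -> dict:
    """SD of lambda_3 among low-MAF versus high-MAF repeating SNPs at small n.

    Sparse genotype classes of a low-MAF repeating SNP make its product terms
    sensitive to a handful of subjects, widening the lambda_3 distribution.
    """
    if study is None:
        study = null_lambda_study(n, seed, genome_size, n_phenotypes)
    lam = study.lambda_values
    maf = study.repeating_mafs
    low = lam[maf <= low_cut]
    high = lam[maf >= high_cut]
    return {
        "sd_lambda_low_maf": float(np.std(low, ddof=1)),
        "sd_lambda_high_maf": float(np.std(high, ddof=1)),
        "n_low": int(low.size),
        "n_high": int(high.size),
    }


def hc3_vs_ols_lambda_range(seed: int, n: int = 1053, genome_size: int = 2000,
                            n_phenotypes: int = 5) -> dict:
    """Range of lambda_3 under HC3 versus OLS, both with the five-subject
    minimum cell count so the comparison is fair.

    The leverage-adjusted sandwich standard errors absorb the stochastic
    heteroskedasticity that drives lambda_3 inflation/deflation, narrowing the
    across-scan range relative to OLS.
    """
    out = {}
    for est in ("OLS", "HC3"):
        cfg = ScanConfig(estimator=est, maf_threshold=0.05, min_cell_count=5)
        study = null_lambda_study(n, seed, genome_size, n_phenotypes, config=cfg)
        lam = study.lambda_values
        out[f"lambda_range_{est.lower()}"] = float(lam.max() - lam.min())
        out[f"lambda_values_{est.lower()}"] = lam
    out["n_scans"] = len(out["lambda_values_ols"])
    return out


def sparse_cell_outliers(seed: int, n: int = 1053, genome_size: int = 4000,
                         n_phenotypes: int = 9, rep_maf: float = 0.06,
                         outlier_threshold: float = 1e-5) -> dict:
    """P-value outliers from HC3 without cell filtering on a sparse genome.

    Scans one low-MAF repeating SNP against a genome including SNPs down to
    MAF 0.01 for each of nine phenotypes, with no minimum cell count, so some
    two-locus cells hold only a couple of subjects.  The
    sandwich variance estimate then rests on a handful of residuals and can
    collapse, yielding spuriously extreme P-values under HC3 that OLS does not
    produce.
    """
    spectrum = MafSpectrum.grid(0.01, 0.5, 0.01)
    mafs = expand_maf_spectrum(spectrum, 0, seed)
    reps = int(np.ceil(genome_size / mafs.size))
    genome_mafs = np.tile(mafs, reps)[:genome_size]
    genome = simulate_genotypes(n, genome_mafs, seed=seed)
    repeating = simulate_genotypes(n, [rep_maf], seed=seed + 1, repeating=True)
    merged = concat_snps(genome, repeating)
    phenotypes = simulate_phenotypes(n, n_phenotypes, seed=seed + 2)
    counts = {}
    for est in ("OLS", "HC3"):
        cfg = ScanConfig(estimator=est, maf_threshold=0.01, min_cell_count=0)
        study = run_study(merged, repeating.snp_ids, phenotypes, cfg, keep_rows=True)
        pvals = np.array(
            [r.p_value for rows in study.scan_rows.values() for r in rows if r.skip_reason == "none"]
        )
        counts[est] = {
            "n_outliers": int(np.sum(pvals < outlier_threshold)),
            "n_tests": int(pvals.size),
        }
    return {
        "outliers_ols": counts["OLS"]["n_outliers"],
        "outliers_hc3": counts["HC3"]["n_outliers"],
        "n_tests": counts["OLS"]["n_tests"],
        "threshold": outlier_threshold,
    }


def heteroskedasticity_direction(seed: int, n: int = 1053, genome_size: int = 1000,
                                 n_phenotypes: int = 10, rep_maf: float = 0.06,
                                 sd_low_in_large: tuple = (0.8, 1.0, 1.3)) -> dict:
    """Median lambda_3 under injected per-genotype-class phenotype variance.

    ``sd_low_in_large`` gives per-dosage standard deviations with the largest
    class (dosage 0 at MAF < 0.5) least variable — the configuration that
    inflates lambda_3; the mirrored structure deflates it.
    """
    mafs = expand_maf_spectrum(GENOME_SPECTRUM, 0, seed)
    reps = int(np.ceil(genome_size / mafs.size))
    genome_mafs = np.tile(mafs, reps)[:genome_size]
    genome = simulate_genotypes(n, genome_mafs, seed=seed)
    repeating = simulate_genotypes(n, [rep_maf], seed=seed + 1, repeating=True)
    merged = concat_snps(genome, repeating)
    x_rep = merged.dosages[:, merged.snp_ids.index(repeating.snp_ids[0])]
    cfg = ScanConfig(estimator="OLS", maf_threshold=0.05, min_cell_count=0)
    out = {}
    mirrored = tuple(reversed(sd_low_in_large))
    for label, sds, s in (("inflate", sd_low_in_large, 3), ("deflate", mirrored, 4)):
        pt = simulate_variance_structured_phenotypes(x_rep, n_phenotypes, sds, seed=seed + s)
        study = run_study(merged, repeating.snp_ids, pt, cfg, keep_rows=False)
        out[f"median_lambda_{label}"] = float(
            np.median([r.lambda_value for r in study.lambda_records])
        )
    out["n_scans_per_direction"] = n_phenotypes
    return out


def compare_lambda_calibration(seed: int, n: int = 300, genome_size: int = 200,
                               rep_maf: float = 0.3, n_null_datasets: int = 8,
                               phenos_per_null: int = 50, n_replicates: int = 200) -> dict:
    """Self-calibration of the empirical-null comparison.

    Null lambda values are pooled from several independent matched datasets
    (lambdas from one dataset share its genome and are correlated, so pooling
    across datasets raises the effective size of the null sample);
    each replicate then draws a fresh dataset from the same generator, scans
    it once, and records the percentile of its lambda within the pooled null.
    If the comparison is calibrated the percentiles are uniform.
    """
    rep_grid = MafSpectrum.grid(rep_maf, rep_maf, 1.0)  # single repeating MAF
    cfg = ScanConfig(estimator="OLS", maf_threshold=0.05, min_cell_count=0)
    null_vals, null_mafs = [], []
    for d in range(n_null_datasets):
        dist = build_null_distribution(
            n=n, genome_size=genome_size, maf_spectrum=GENOME_SPECTRUM,
            repeating_grid=rep_grid, n_phenotypes=phenos_per_null,
            config=cfg, seed=seed + 10 + d,
        )
        null_vals.append(dist.lambda_values)
        null_mafs.append(dist.repeating_mafs)
    from .empirical_null import NullLambdaDistribution

    pooled = NullLambdaDistribution(
        lambda_values=np.concatenate(null_vals),
        repeating_mafs=np.concatenate(null_mafs),
        phenotype_ids=[],
        generating_config={"pooled_from": n_null_datasets, "seed": seed},
    )
    percentiles = np.empty(n_replicates)
    for r in range(n_replicates):
        dist = build_null_distribution(
            n=n, genome_size=genome_size, maf_spectrum=GENOME_SPECTRUM,
            repeating_grid=rep_grid, n_phenotypes=1,
            config=cfg, seed=seed + 1000 + r,
        )
        res = compare_lambda(float(dist.lambda_values[0]), pooled, maf_matching="all")
        percentiles[r] = res["percentile"]
    ks_stat, ks_p = stats.kstest(percentiles / 100.0, "uniform")
    return {
        "ks_statistic": float(ks_stat),
        "ks_p_value": float(ks_p),
        "n_replicates": n_replicates,
        "n_null": int(pooled.lambda_values.size),
        "percentiles": percentiles,
    }


def study_cardinality(seed: int, n: int = 150, genome_size: int = 60,
                      n_phenotypes: int = 9) -> dict:
    """Scan count of a full-cardinality study: a repeating-SNP MAF grid of
    0.05-0.5 in steps of 0.01 (46 SNPs) crossed with the phenotypes, on a toy
    genome."""
    rep_grid = MafSpectrum.grid(0.05, 0.5, 0.01)
    cfg = ScanConfig(estimator="OLS", maf_threshold=0.05, min_cell_count=0)
    dist = build_null_distribution(
        n=n, genome_size=genome_size, maf_spectrum=GENOME_SPECTRUM,
        repeating_grid=rep_grid, n_phenotypes=n_phenotypes, config=cfg, seed=seed,
    )
    return {
        "n_repeating": len(expand_maf_spectrum(rep_grid, 0, seed)),
        "n_phenotypes": n_phenotypes,
        "n_scans": dist.n_scans,
    }
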