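"""Scan engine: recoding, filters, per-pair rows, and study-level behaviour."""

import numpy as np
import pytest

from interscan.inflation import observed_alpha
from interscan.scan import (
    ScanConfig,
    ScanError,
    apply_min_cell_filter,
    filter_maf,
    minor_allele_recode,
    recode_matrix,
    rows_to_dataframe,
    run_study,
    scan_pairs,
    two_locus_cell_counts,
)
from interscan.simulate import MISSING, GenotypeMatrix, simulate_genotypes, simulate_phenotypes

from conftest import build_dataset


def counts_to_vector(n0, n1, n2):
    return np.repeat([0, 1, 2], [n0, n1, n2]).astype(np.int8)


class TestMinorAlleleRecode:
    def test_already_minor_coded_unchanged(self):
        g, maf = minor_allele_recode(np.array([0, 0, 1], dtype=np.int8))
        assert np.array_equal(g, [0, 0, 1])
        assert maf == pytest.approx(1 / 6)

    def test_major_coded_flipped(self):
        g, maf = minor_allele_recode(np.array([2, 2, 1], dtype=np.int8))
        assert np.array_equal(g, [0, 0, 1])
        assert maf == pytest.approx(1 / 6)

    def test_reference_cohort_counts_reproduce_printed_maf(self):
        # 295/537/221 in 1,053 subjects -> MAF 0.46 at two decimals
        g, maf = minor_allele_recode(counts_to_vector(295, 537, 221))
        assert round(maf, 2) == 0.46

    def test_missing_preserved_and_excluded_from_frequency(self):
        g = np.array([2, 2, 1, MISSING], dtype=np.int8)
        rec, maf = minor_allele_recode(g)
        assert rec[3] == MISSING
        assert maf == pytest.approx(1 / 6)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            minor_allele_recode(np.full(5, MISSING, dtype=np.int8))


class TestFilters:
    def _matrix(self, mafs):
        cols = [counts_to_vector(*np.random.default_rng(1).multinomial(100, [(1 - m) ** 2, 2 * m * (1 - m), m**2])) for m in mafs]
        return GenotypeMatrix(
            dosages=np.column_stack(cols),
            snp_ids=[f"s{i}" for i in range(len(mafs))],
            snp_maf=np.array(mafs),
            repeating_flags=np.zeros(len(mafs), dtype=bool),
        )

    def test_zero_threshold_is_identity(self):
        gm = self._matrix([0.005, 0.01, 0.3])
        assert filter_maf(gm, 0.0).n_snps == 3

    def test_threshold_is_inclusive(self):
        gm = self._matrix([0.005, 0.01, 0.3])
        kept = filter_maf(gm, 0.01)
        assert kept.snp_ids == ["s1", "s2"]

    def test_simulated_grid_spectrum_mostly_survives_own_threshold(self):
        from interscan.simulate import MafSpectrum, expand_maf_spectrum

        grid = expand_maf_spectrum(MafSpectrum.grid(0.05, 0.5, 0.01), 0, seed=0)
        mafs = np.tile(grid, 44)[:2000]
        gm = simulate_genotypes(1053, mafs, seed=3)
        gm = recode_matrix(gm)
        # SNPs simulated exactly at the 0.05 boundary (44 of 2000 here) land
        # below it in the realized sample about half the time (SE of the
        # sample MAF ~0.0047 at n=1053), so expected retention is ~98.9%;
        # SNPs clear of the boundary are essentially always retained
        retained = filter_maf(gm, 0.05)
        assert retained.n_snps >= 0.98 * 2000
        se = np.sqrt(0.05 * 0.95 / (2 * 1053))
        clear = mafs >= 0.05 + 3 * se  # generating MAF well above the boundary
        assert gm.snp_maf[clear].min() >= 0.05


class TestCellCounts:
    def test_direct_tally(self):
        counts = two_locus_cell_counts(np.array([0, 0, 1, 2]), np.array([0, 1, 0, 2]))
        expected = np.zeros((3, 3), dtype=int)
        expected[0, 0] = expected[0, 1] = expected[1, 0] = expected[2, 2] = 1
        assert np.array_equal(counts, expected)

    def test_grand_total_conserved(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 3, 500)
        z = rng.integers(0, 3, 500)
        assert two_locus_cell_counts(x, z).sum() == 500

    def test_independent_snps_follow_product_multinomial(self):
        n = 50_000
        gm = simulate_genotypes(n, [0.3, 0.4], seed=6)
        x, z = gm.dosages[:, 0], gm.dosages[:, 1]
        counts = two_locus_cell_counts(x, z)
        px = np.bincount(x, minlength=3) / n
        pz = np.bincount(z, minlength=3) / n
        expected = n * np.outer(px, pz)
        se = np.sqrt(expected * (1 - np.outer(px, pz)))
        assert np.all(np.abs(counts - expected) < 3 * se + 3)


class TestMinCellFilter:
    def test_sparse_cell_subjects_dropped(self):
        x = np.repeat([0, 0, 1], [10, 6, 4]).astype(np.int8)
        z = np.repeat([0, 1, 1], [10, 6, 4]).astype(np.int8)
        y = np.arange(20.0)
        fx, fz, fy, dropped = apply_min_cell_filter(x, z, y, 5)
        assert dropped == 4
        assert len(fy) == 16
        assert not np.any((fx == 1) & (fz == 1))

    def test_no_sparse_cells_identity(self):
        x = np.repeat([0, 1], 10).astype(np.int8)
        z = np.tile([0, 1], 10).astype(np.int8)
        y = np.arange(20.0)
        fx, fz, fy, dropped = apply_min_cell_filter(x, z, y, 5)
        assert dropped == 0 and np.array_equal(fy, y)

    def test_zero_minimum_identity(self):
        x = np.array([0, 1, 2], dtype=np.int8)
        z = np.array([0, 0, 0], dtype=np.int8)
        _, _, fy, dropped = apply_min_cell_filter(x, z, np.arange(3.0), 0)
        assert dropped == 0 and len(fy) == 3

    def test_single_pass_no_reevaluation(self):
        # after dropping the 4-subject cell, the (0,1) cell falls to 4 as well
        # in a re-evaluation scheme; single-pass keeps it
        x = np.repeat([0, 0, 1], [10, 5, 4]).astype(np.int8)
        z = np.repeat([0, 1, 1], [10, 5, 4]).astype(np.int8)
        _, fz, fy, dropped = apply_min_cell_filter(x, z, np.arange(19.0), 5)
        assert dropped == 4
        assert np.sum(fz == 1) == 5


class TestScanPairs:
    def test_row_per_passing_snp_and_conservation(self, small_dataset, ols_config):
        merged, rep_ids, phenos = small_dataset
        rows = scan_pairs(merged, rep_ids[0], phenos.values[:, 0], ols_config)
        assert len(rows) > 0
        for r in rows:
            assert r.n_used + r.n_dropped == r.cell_counts.sum()
        # row count equals SNPs passing the MAF filter, repeating excluded
        prepared = filter_maf(recode_matrix(merged), 0.05, keep_repeating=True)
        n_passing = int(np.sum(~prepared.repeating_flags))
        assert len(rows) == n_passing

    def test_deterministic_archives(self, small_dataset, ols_config):
        merged, rep_ids, phenos = small_dataset
        a = rows_to_dataframe(scan_pairs(merged, rep_ids[0], phenos.values[:, 0], ols_config))
        b = rows_to_dataframe(scan_pairs(merged, rep_ids[0], phenos.values[:, 0], ols_config))
        assert a.equals(b)

    def test_monomorphic_repeating_aborts_scan(self, ols_config):
        gm = simulate_genotypes(100, [0.3, 0.2], seed=8)
        gm.repeating_flags[1] = True
        gm.dosages[:, 1] = 0
        with pytest.raises(ScanError):
            scan_pairs(gm, gm.snp_ids[1], np.random.default_rng(0).standard_normal(100), ScanConfig(maf_threshold=0.0))

    def test_monomorphic_nonrepeating_becomes_skip_row(self):
        n = 60
        gm = simulate_genotypes(n, [0.3, 0.4], seed=9)
        gm.dosages[:, 0] = 0  # monomorphic non-repeating SNP
        gm.repeating_flags[1] = True
        cfg = ScanConfig(maf_threshold=0.0, min_cell_count=0)
        rows = scan_pairs(gm, gm.snp_ids[1], np.random.default_rng(1).standard_normal(n), cfg)
        assert rows[0].skip_reason == "monomorphic"
        assert np.isnan(rows[0].statistic)

    def test_missing_genotypes_complete_cased_per_pair(self):
        n = 200
        gm = simulate_genotypes(n, [0.3, 0.4, 0.35], seed=10)
        gm.repeating_flags[2] = True
        gm.dosages[:5, 0] = MISSING
        cfg = ScanConfig(maf_threshold=0.0, min_cell_count=0)
        rows = scan_pairs(gm, gm.snp_ids[2], np.random.default_rng(2).standard_normal(n), cfg)
        by_id = {r.nonrepeating_snp_id: r for r in rows}
        assert by_id[gm.snp_ids[0]].cell_counts.sum() == n - 5
        assert by_id[gm.snp_ids[1]].cell_counts.sum() == n

    def test_null_scan_observed_alpha_in_plausible_band(self):
        merged, rep_ids = build_dataset(1053, np.linspace(0.05, 0.5, 1000), [0.25], seed=31)
        phenos = simulate_phenotypes(1053, 1, seed=32)
        cfg = ScanConfig(estimator="OLS", maf_threshold=0.05, min_cell_count=0)
        rows = scan_pairs(merged, rep_ids[0], phenos.values[:, 0], cfg)
        p = [r.p_value for r in rows if r.skip_reason == "none"]
        assert 0.03 <= observed_alpha(p) <= 0.09


class TestRunStudy:
    def test_cardinality_one_by_one(self, ols_config):
        merged, rep_ids = build_dataset(150, np.linspace(0.1, 0.5, 50), [0.3], seed=33)
        phenos = simulate_phenotypes(150, 1, seed=34)
        study = run_study(merged, rep_ids, phenos, ols_config)
        assert len(study.lambda_records) == 1
        assert study.lambda_records[0].n_tests <= 50

    def test_cardinality_cross_product(self, ols_config):
        merged, rep_ids = build_dataset(150, np.linspace(0.1, 0.5, 40), [0.2, 0.3, 0.4], seed=35)
        phenos = simulate_phenotypes(150, 4, seed=36)
        study = run_study(merged, rep_ids, phenos, ols_config)
        assert len(study.lambda_records) == 12
        assert not study.failures

    def test_failures_recorded_not_fatal(self, ols_config):
        merged, rep_ids = build_dataset(150, np.linspace(0.1, 0.5, 40), [0.3, 0.4], seed=37)
        merged.dosages[:, merged.snp_ids.index(rep_ids[0])] = 0  # kill one repeating SNP
        phenos = simulate_phenotypes(150, 2, seed=38)
        study = run_study(merged, rep_ids, phenos, ols_config)
        assert len(study.lambda_records) == 2  # surviving repeating SNP x 2 phenotypes
        assert len(study.failures) == 2

    def test_aggregated_null_pvalues_uniform(self):
        # large-n OLS null: P-values across a small study are KS-uniform
        from scipy import stats

        merged, rep_ids = build_dataset(10_000, np.linspace(0.1, 0.5, 400), [0.3, 0.45], seed=39)
        phenos = simulate_phenotypes(10_000, 2, seed=40)
        cfg = ScanConfig(estimator="OLS", maf_threshold=0.05, min_cell_count=0)
        study = run_study(merged, rep_ids, phenos, cfg, keep_rows=True)
        p = np.array([r.p_value for rows in study.scan_rows.values() for r in rows if r.skip_reason == "none"])
        assert stats.kstest(p, "uniform").pvalue > 0.001

    def test_two_locus_beta2_matches_main_effect_beta1(self):
        # with the repeating SNP independent of z, adjusting for it barely
        # moves the non-repeating SNP's statistic
        merged, rep_ids = build_dataset(1000, np.linspace(0.1, 0.5, 300), [0.3], seed=41)
        phenos = simulate_phenotypes(1000, 1, seed=42)
        y = phenos.values[:, 0]
        cfg2 = ScanConfig(model_id="II", test_spec="beta2_2locus", maf_threshold=0.05, min_cell_count=0)
        cfg1 = ScanConfig(model_id="I", test_spec="beta1_main", maf_threshold=0.05, min_cell_count=0)
        t2 = np.array([r.statistic for r in scan_pairs(merged, rep_ids[0], y, cfg2) if r.skip_reason == "none"])
        t1 = np.array([r.statistic for r in scan_pairs(merged, rep_ids[0], y, cfg1) if r.skip_reason == "none"])
        assert np.corrcoef(t1, t2)[0, 1] > 0.99
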