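"""SNP-by-genome interaction scan engine.

A scan holds one "repeating" SNP fixed and iterates every "non-repeating" SNP
through the genome, fitting the configured model to each pair and testing the
requested hypothesis.  Filtering proceeds in a fixed order:

1. minor-allele recode of every SNP on the full analyzed sample,
2. genome-wide MAF threshold on the non-repeating SNPs,
3. per-pair complete-case subset (subjects missing either SNP are dropped
   for that pair only),
4. per-pair minimum-cell-count filter: subjects in populated two-locus
   genotype cells smaller than the minimum are dropped (single pass — counts
   are not re-evaluated after dropping; empty cells impose no constraint),
5. model fit and test.

MAF is not recomputed after per-pair subject drops.  Degenerate pairs become
skip rows with a reason and never abort the scan.  By default no minimum cell
count is applied with OLS standard errors, while the heteroskedasticity-
consistent estimators default to a five-subject minimum, the guard against the
sandwich instability caused by sparse two-locus cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import regression as reg
from .inflation import LambdaRecord, lambda_from_pvalues, lambda_from_tstats, observed_alpha
from .simulate import MISSING, GenotypeMatrix, PhenotypeTable

__all__ = [
    "ScanConfig",
    "ScanRow",
    "StudyResult",
    "ScanError",
    "minor_allele_recode",
    "recode_matrix",
    "filter_maf",
    "two_locus_cell_counts",
    "apply_min_cell_filter",
    "scan_pairs",
    "run_study",
    "rows_to_dataframe",
]

#: test_spec -> (model_id, kind, target labels)
_TESTS: dict[str, tuple[str, str, list[str]]] = {
    "beta3_1df": ("III", "wald", ["product"]),
    "joint_rep_2df": ("III", "f", ["rep_additive", "product"]),
    "joint_nonrep_2df": ("III", "f", ["nonrep_additive", "product"]),
    "interaction_4df": ("IV", "f", ["prod_aa", "prod_ad", "prod_da", "prod_dd"]),
    "beta2_2locus": ("II", "wald", ["nonrep_additive"]),
    "beta1_main": ("I", "wald", ["nonrep_additive"]),
}


class ScanError(RuntimeError):
    """A whole scan cannot run (e.g. the repeating SNP is monomorphic)."""


@dataclass(frozen=True)
class ScanConfig:
    """Settings for one scan or study.

    ``min_cell_count=None`` resolves to 0 for OLS and 5 for HC0/HC3.
    Multi-df (F) tests are available with OLS inference only; the sandwich
    estimators apply to single-coefficient Wald tests.
    """

    model_id: str = "III"
    test_spec: str = "beta3_1df"
    estimator: str = "OLS"
    maf_threshold: float = 0.05
    min_cell_count: int | None = None
    alpha_level: float = 0.05
    denominator: str = "exact_chisq1_median"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.test_spec not in _TESTS:
            raise ValueError(f"unknown test_spec {self.test_spec!r}")
        model_required, kind, _ = _TESTS[self.test_spec]
        if self.model_id != model_required:
            raise ValueError(
                f"test {self.test_spec!r} requires model {model_required}, got {self.model_id}"
            )
        if self.estimator not in ("OLS", "HC0", "HC3"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if kind == "f" and self.estimator != "OLS":
            raise ValueError("multi-df F tests are available with OLS only")
        if not 0.0 <= self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must lie in [0, 0.5)")
        if self.min_cell_count is not None and self.min_cell_count < 0:
            raise ValueError("min_cell_count must be non-negative")

    @property
    def resolved_min_cell(self) -> int:
        if self.min_cell_count is not None:
            return self.min_cell_count
        return 0 if self.estimator == "OLS" else 5


@dataclass
class ScanRow:
    """Per SNP-pair output of one scan."""

    repeating_snp_id: str
    nonrepeating_snp_id: str
    n_used: int
    n_dropped: int
    cell_counts: np.ndarray  # 3x3 complete-case counts, before cell filtering
    beta: float = np.nan
    se: float = np.nan
    statistic: float = np.nan
    p_value: float = np.nan
    df_num: int = 0
    df_den: int = 0
    skip_reason: str = "none"  # none | monomorphic | singular | insufficient_cells


@dataclass
class StudyResult:
    """All scans of a study: lambda records plus the full per-pair archive."""

    lambda_records: list[LambdaRecord]
    scan_rows: dict[tuple[str, str], list[ScanRow]]
    failures: list[tuple[str, str, str]]  # (repeating id, phenotype id, message)
    config: ScanConfig


def minor_allele_recode(dosages: np.ndarray) -> tuple[np.ndarray, float]:
    """Flip a dosage vector so it counts the minor allele; return it with its MAF.

    The frequency of the counted allele is computed on non-missing entries of
    the analyzed sample; if it exceeds 0.5 every genotype is reflected
    (g -> 2 - g).
    """
    g = np.asarray(dosages)
    obs = g != MISSING
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise ValueError("all genotypes missing; cannot recode")
    freq = float(g[obs].sum()) / (2.0 * n_obs)
    if freq > 0.5:
        flipped = g.copy()
        flipped[obs] = 2 - flipped[obs]
        return flipped, 1.0 - freq
    return g, freq


def recode_matrix(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Minor-allele recode every SNP on the full analyzed sample."""
    dosages = genotypes.dosages.copy()
    mafs = np.empty(genotypes.n_snps)
    for j in range(genotypes.n_snps):
        dosages[:, j], mafs[j] = minor_allele_recode(dosages[:, j])
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=list(genotypes.snp_ids),
        snp_maf=mafs,
        repeating_flags=genotypes.repeating_flags.copy(),
        subject_ids=list(genotypes.subject_ids),
    )


def filter_maf(genotypes: GenotypeMatrix, threshold: float, keep_repeating: bool = False) -> GenotypeMatrix:
    """Retain SNPs with MAF >= threshold (inclusive), preserving order.

    With ``keep_repeating`` the repeating-flagged SNPs bypass the threshold so
    they stay addressable by a scan.
    """
    keep = genotypes.snp_maf >= threshold
    if keep_repeating:
        keep |= genotypes.repeating_flags
    idx = np.where(keep)[0]
    return GenotypeMatrix(
        dosages=genotypes.dosages[:, idx],
        snp_ids=[genotypes.snp_ids[i] for i in idx],
        snp_maf=genotypes.snp_maf[idx],
        repeating_flags=genotypes.repeating_flags[idx],
        subject_ids=list(genotypes.subject_ids),
    )


def two_locus_cell_counts(x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts: counts[i, j] = #{x = i and z = j}."""
    x = np.asarray(x)
    z = np.asarray(z)
    if x.shape != z.shape:
        raise ValueError("dosage vectors differ in length")
    return np.bincount(3 * x.astype(np.intp) + z.astype(np.intp), minlength=9).reshape(3, 3)


def apply_min_cell_filter(x, z, y, min_count: int):
    """Drop subjects in populated two-locus cells smaller than ``min_count``.

    Counts are computed once on the input (single pass); cells left sparse by
    the dropping are not re-examined, and empty cells impose no constraint.
    Returns (x, z, y, n_dropped).
    """
    x = np.asarray(x)
    z = np.asarray(z)
    y = np.asarray(y)
    if min_count <= 0:
        return x, z, y, 0
    cell = 3 * x.astype(np.intp) + z.astype(np.intp)
    counts = np.bincount(cell, minlength=9)
    bad = (counts > 0) & (counts < min_count)
    if not bad.any():
        return x, z, y, 0
    keep = ~bad[cell]
    return x[keep], z[keep], y[keep], int((~keep).sum())


def _prepare(genotypes: GenotypeMatrix, config: ScanConfig) -> GenotypeMatrix:
    return filter_maf(recode_matrix(genotypes), config.maf_threshold, keep_repeating=True)


def _fit_and_test(x, z, y, config: ScanConfig):
    """Fit the configured model on one filtered pair; return row fields.

    P-values are left NaN here and filled in batch by the caller — the scalar
    scipy survival-function call dominates the per-pair cost otherwise.
    """
    model_id, kind, targets = _TESTS[config.test_spec]
    design = reg.build_design(model_id, x if model_id != "I" else None, z)
    fit = reg.fit_ols(design, y)
    if kind == "wald":
        cov = reg.covariance(fit, design, config.estimator)
        j = design.column_labels.index(targets[0])
        var = cov.matrix[j, j]
        if var <= 0.0:
            raise reg.DegenerateTestError(f"non-positive variance for {targets[0]}")
        se = float(np.sqrt(var))
        return dict(
            beta=float(fit.beta_hat[j]),
            se=se,
            statistic=float(fit.beta_hat[j] / se),
            p_value=np.nan,
            df_num=1,
            df_den=fit.n_used - fit.k,
        )
    labels = design.column_labels
    keep = [i for i, lab in enumerate(labels) if lab not in targets]
    reduced = reg.DesignMatrix(columns=design.columns[:, keep],
                               column_labels=[labels[i] for i in keep],
                               model_id=model_id)
    fit_red = reg.fit_ols(reduced, y)
    q = len(targets)
    df_den = fit.n_used - fit.k
    fstat = ((fit_red.rss - fit.rss) / q) / (fit.rss / df_den)
    return dict(
        beta=np.nan,
        se=np.nan,
        statistic=float(fstat),
        p_value=np.nan,
        df_num=q,
        df_den=df_den,
    )


def _fill_p_values(rows: list[ScanRow], kind: str) -> None:
    """Vectorised P-value computation over all non-skipped rows of a scan."""
    from scipy import stats

    ok = [r for r in rows if r.skip_reason == "none"]
    if not ok:
        return
    stat = np.array([r.statistic for r in ok])
    df_den = np.array([r.df_den for r in ok])
    if kind == "wald":
        p = 2.0 * stats.t.sf(np.abs(stat), df_den)
    else:
        df_num = np.array([r.df_num for r in ok])
        p = stats.f.sf(stat, df_num, df_den)
    for r, pv in zip(ok, p):
        r.p_value = float(pv)


def scan_pairs(
    genotypes: GenotypeMatrix,
    repeating_id: str,
    phenotype: np.ndarray,
    config: ScanConfig,
    _prepared: bool = False,
) -> list[ScanRow]:
    """One SNP-by-genome scan: the repeating SNP against every non-repeating SNP.

    Emits one :class:`ScanRow` per non-repeating SNP passing the MAF filter
    (the repeating SNP itself excluded; SNPs correlated with it are *not*
    excluded).  Degenerate pairs yield skip rows; a monomorphic repeating SNP
    aborts the whole scan with :class:`ScanError`.
    """
    if not _prepared:
        genotypes = _prepare(genotypes, config)
    phenotype = np.asarray(phenotype, dtype=float)
    if phenotype.shape[0] != genotypes.n_subjects:
        raise ValueError("phenotype length does not match subjects")
    rep_idx = genotypes.snp_ids.index(repeating_id)
    x_all = genotypes.dosages[:, rep_idx]
    if len(np.unique(x_all[x_all != MISSING])) < 2:
        raise ScanError(f"repeating SNP {repeating_id} is monomorphic")
    k_model = len(reg.MODEL_COLUMNS[_TESTS[config.test_spec][0]])
    min_cell = config.resolved_min_cell
    has_missing = bool((genotypes.dosages == MISSING).any())
    y_ok = np.isfinite(phenotype)

    rows: list[ScanRow] = []
    for j in range(genotypes.n_snps):
        if j == rep_idx or genotypes.repeating_flags[j]:
            continue
        z_all = genotypes.dosages[:, j]
        snp_id = genotypes.snp_ids[j]
        if has_missing or not y_ok.all():
            cc = (x_all != MISSING) & (z_all != MISSING) & y_ok
            x, z, y = x_all[cc], z_all[cc], phenotype[cc]
        else:
            x, z, y = x_all, z_all, phenotype
        counts = two_locus_cell_counts(x, z)
        n_cc = int(counts.sum())
        x, z, y, dropped = apply_min_cell_filter(x, z, y, min_cell)
        row = ScanRow(
            repeating_snp_id=repeating_id,
            nonrepeating_snp_id=snp_id,
            n_used=len(y),
            n_dropped=dropped,
            cell_counts=counts,
        )
        assert row.n_used + dropped == n_cc
        if len(y) < k_model + 1:
            row.skip_reason = "insufficient_cells"
            rows.append(row)
            continue
        if (z == z[0]).all() or (x == x[0]).all():
            row.skip_reason = "monomorphic"
            rows.append(row)
            continue
        try:
            fields = _fit_and_test(x, z, y, config)
        except (reg.SingularDesignError, reg.DegenerateTestError):
            row.skip_reason = "singular"
            rows.append(row)
            continue
        for name, val in fields.items():
            setattr(row, name, val)
        rows.append(row)
    _fill_p_values(rows, _TESTS[config.test_spec][1])
    return rows


def _lambda_record(rows: list[ScanRow], rep_id: str, rep_maf: float, pheno_id: str, config: ScanConfig) -> LambdaRecord:
    ok = [r for r in rows if r.skip_reason == "none"]
    n_skipped = len(rows) - len(ok)
    if not ok:
        raise ScanError(f"scan ({rep_id}, {pheno_id}) produced no usable tests")
    pvals = np.array([r.p_value for r in ok])
    if config.test_spec in ("beta3_1df", "beta2_2locus", "beta1_main"):
        lam = lambda_from_tstats([r.statistic for r in ok], config.denominator)
        source = "t_squared"
    else:
        lam = lambda_from_pvalues(pvals, config.denominator)
        source = "chisq_from_p"
    return LambdaRecord(
        lambda_value=lam,
        source=source,
        estimator=config.estimator,
        model_id=config.model_id,
        test_df=ok[0].df_num,
        repeating_snp_id=rep_id,
        repeating_maf=rep_maf,
        phenotype_id=pheno_id,
        n_tests=len(ok),
        observed_alpha=observed_alpha(pvals, config.alpha_level),
        n_skipped=n_skipped,
        denominator_mode=config.denominator,
    )


def run_study(
    genotypes: GenotypeMatrix,
    repeating_ids: list[str],
    phenotypes: PhenotypeTable,
    config: ScanConfig,
    keep_rows: bool = True,
) -> StudyResult:
    """Run one scan per (repeating SNP, phenotype) and collect lambda records.

    Scan-level failures are recorded and do not abort the study.  With
    ``keep_rows=False`` the per-pair archive is discarded after each scan's
    lambda is computed (useful for large simulation studies).
    """
    prepared = _prepare(genotypes, config)
    records: list[LambdaRecord] = []
    archive: dict[tuple[str, str], list[ScanRow]] = {}
    failures: list[tuple[str, str, str]] = []
    for rep_id in repeating_ids:
        if rep_id not in prepared.snp_ids:
            failures.append((rep_id, "*", "repeating SNP not present after filtering"))
            continue
        rep_maf = float(prepared.snp_maf[prepared.snp_ids.index(rep_id)])
        for t, pheno_id in enumerate(phenotypes.trait_ids):
            y = phenotypes.values[:, t]
            try:
                rows = scan_pairs(prepared, rep_id, y, config, _prepared=True)
                records.append(_lambda_record(rows, rep_id, rep_maf, pheno_id, config))
            except ScanError as exc:
                failures.append((rep_id, pheno_id, str(exc)))
                continue
            if keep_rows:
                archive[(rep_id, pheno_id)] = rows
    return StudyResult(lambda_records=records, scan_rows=archive, failures=failures, config=config)


def rows_to_dataframe(rows: list[ScanRow]):
    """Flatten ScanRows to a pandas DataFrame (cell counts as c00..c22)."""
    import pandas as pd

    recs = []
    for r in rows:
        d = {
            "repeating_snp_id": r.repeating_snp_id,
            "nonrepeating_snp_id": r.nonrepeating_snp_id,
            "n_used": r.n_used,
            "n_dropped": r.n_dropped,
            "beta": r.beta,
            "se": r.se,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "df_num": r.df_num,
            "df_den": r.df_den,
            "skip_reason": r.skip_reason,
        }
        for i in range(3):
            for j in range(3):
                d[f"c{i}{j}"] = int(r.cell_counts[i, j])
        recs.append(d)
    return pd.DataFrame(recs)
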