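"""Null-hypothesis dataset simulation.

Generates genotype matrices under Hardy-Weinberg equilibrium from a minor-allele
frequency (MAF) spectrum, and quantitative phenotypes that carry no SNP effects:
either fresh standard-normal draws or independently permuted copies of supplied
trait columns.  Deliberately excluded, because the null model excludes them:
linkage disequilibrium, population substructure, relatedness, and any genotype
effect on the phenotype mean.

Random-number discipline: every public generator takes a single master ``seed``;
per-SNP and per-trait substreams are derived with :class:`numpy.random.SeedSequence`
so that regenerating one column is reproducible without regenerating the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MISSING",
    "MafSpectrum",
    "GenotypeMatrix",
    "PhenotypeTable",
    "expand_maf_spectrum",
    "hwe_genotype_freqs",
    "simulate_genotypes",
    "simulate_phenotypes",
    "permute_phenotypes",
    "default_maf_spectrum",
]

#: Sentinel for a missing genotype dosage (matrices are small-integer typed).
MISSING: int = -1

# Stream tags keeping genotype / phenotype / permutation substreams disjoint
# even when the same master seed is reused across generator calls.
_GENO_STREAM = 11
_PHENO_STREAM = 23
_PERMUTE_STREAM = 37


class ConfigurationError(ValueError):
    """Invalid simulation configuration (bad spectrum, step, or value list)."""


@dataclass(frozen=True)
class MafSpectrum:
    """A source of minor-allele frequencies, either a grid or an empirical list.

    Grid mode enumerates an inclusive arithmetic sequence of frequencies;
    empirical mode resamples (with replacement) from a supplied list, e.g. the
    observed MAF distribution of a genotyping panel.
    """

    mode: str  # "grid" | "empirical"
    grid_start: float = 0.0
    grid_end: float = 0.0
    grid_step: float = 0.0
    empirical_values: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.mode not in ("grid", "empirical"):
            raise ConfigurationError(f"unknown MAF spectrum mode {self.mode!r}")
        if self.mode == "grid":
            if self.grid_step <= 0:
                raise ConfigurationError("grid_step must be positive")
            if self.grid_start > self.grid_end:
                raise ConfigurationError("grid_start must not exceed grid_end")
            if not (0.0 < self.grid_start <= 0.5 and 0.0 < self.grid_end <= 0.5):
                raise ConfigurationError("grid endpoints must lie in (0, 0.5]")
        else:
            if not self.empirical_values:
                raise ConfigurationError("empirical spectrum requires a non-empty value list")
            vals = np.asarray(self.empirical_values, dtype=float)
            if np.any(vals <= 0.0) or np.any(vals > 0.5):
                raise ConfigurationError("empirical MAFs must lie in (0, 0.5]")

    @classmethod
    def grid(cls, start: float, end: float, step: float) -> "MafSpectrum":
        return cls(mode="grid", grid_start=start, grid_end=end, grid_step=step)

    @classmethod
    def empirical(cls, values) -> "MafSpectrum":
        return cls(mode="empirical", empirical_values=tuple(float(v) for v in values))


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele dosage matrix with per-SNP metadata.

    ``dosages`` holds integers in {0, 1, 2} with :data:`MISSING` (-1) for
    missing calls.  ``snp_maf`` records the allele frequency each SNP was
    simulated at, or the sample frequency when computed from data.
    ``repeating_flags`` marks SNPs intended to be held fixed across a
    SNP-by-genome scan.
    """

    dosages: np.ndarray
    snp_ids: list[str]
    snp_maf: np.ndarray
    repeating_flags: np.ndarray
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.snp_maf = np.asarray(self.snp_maf, dtype=float)
        self.repeating_flags = np.asarray(self.repeating_flags, dtype=bool)
        n, m = self.dosages.shape
        if not (len(self.snp_ids) == len(self.snp_maf) == len(self.repeating_flags) == m):
            raise ValueError("SNP metadata length does not match dosage columns")
        if self.subject_ids is None:
            self.subject_ids = [f"S{i + 1}" for i in range(n)]
        elif len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match dosage rows")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_ids.index(snp_id)]


@dataclass
class PhenotypeTable:
    """Subjects x traits matrix of quantitative phenotype values."""

    values: np.ndarray
    trait_ids: list[str]
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("phenotype values must be 2-D (subjects x traits)")
        if len(self.trait_ids) != self.values.shape[1]:
            raise ValueError("trait_ids length does not match value columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotype values must be finite")
        if self.subject_ids is None:
            self.subject_ids = [f"S{i + 1}" for i in range(self.values.shape[0])]
        elif len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length does not match value rows")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def column(self, trait_id: str) -> np.ndarray:
        return self.values[:, self.trait_ids.index(trait_id)]


def expand_maf_spectrum(spec: MafSpectrum, m: int, seed: int) -> np.ndarray:
    """Materialise ``m`` allele frequencies from a spectrum.

    Grid mode returns every grid point exactly once (``m`` is ignored); the
    sequence is built with integer index arithmetic so step accumulation cannot
    drift past the inclusive endpoint.  Empirical mode draws ``m`` values
    uniformly with replacement.
    """
    if spec.mode == "grid":
        k = int(round((spec.grid_end - spec.grid_start) / spec.grid_step))
        points = spec.grid_start + spec.grid_step * np.arange(k + 1)
        # guard against a rounding overshoot of the inclusive endpoint
        return points[points <= spec.grid_end + 1e-12]
    if m < 1:
        raise ConfigurationError("m must be at least 1 for empirical spectra")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    vals = np.asarray(spec.empirical_values, dtype=float)
    return rng.choice(vals, size=m, replace=True)


def hwe_genotype_freqs(maf: float) -> tuple[float, float, float]:
    """Genotype class frequencies (f0, f1, f2) under Hardy-Weinberg equilibrium.

    With minor-allele frequency p, the dosage classes 0/1/2 occur with
    probabilities (1-p)^2, 2p(1-p), p^2.
    """
    p = float(maf)
    if not 0.0 <= p <= 0.5:
        raise ValueError(f"MAF must lie in [0, 0.5], got {p}")
    q = 1.0 - p
    return (q * q, 2.0 * p * q, p * p)


def simulate_genotypes(
    n: int,
    mafs,
    seed: int,
    snp_ids: list[str] | None = None,
    repeating: bool = False,
) -> GenotypeMatrix:
    """Draw an n-subject genotype matrix with one SNP per entry of ``mafs``.

    Each dosage is an independent draw from the three-class HWE distribution
    for its SNP's frequency; no missingness, no LD, no substructure.  Each SNP
    uses its own seed substream, so a single column can be regenerated alone.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    mafs = np.asarray(mafs, dtype=float)
    m = mafs.size
    if snp_ids is None:
        prefix = "rep" if repeating else "snp"
        snp_ids = [f"{prefix}{j + 1}" for j in range(m)]
    dosages = np.empty((n, m), dtype=np.int8)
    master = np.random.SeedSequence([int(seed), _GENO_STREAM])
    children = master.spawn(m)
    for j in range(m):
        f0, f1, _ = hwe_genotype_freqs(mafs[j])
        u = np.random.default_rng(children[j]).random(n)
        dosages[:, j] = (u >= f0).astype(np.int8) + (u >= f0 + f1).astype(np.int8)
    flags = np.full(m, bool(repeating))
    return GenotypeMatrix(dosages=dosages, snp_ids=list(snp_ids), snp_maf=mafs, repeating_flags=flags)


def simulate_phenotypes(n: int, q: int, seed: int, trait_ids: list[str] | None = None) -> PhenotypeTable:
    """Draw q independent standard-normal phenotype columns for n subjects."""
    if n < 2:
        raise ValueError("n must be at least 2")
    if q < 1:
        raise ValueError("q must be at least 1")
    if trait_ids is None:
        trait_ids = [f"pheno{j + 1}" for j in range(q)]
    master = np.random.SeedSequence([int(seed), _PHENO_STREAM])
    children = master.spawn(q)
    values = np.column_stack(
        [np.random.default_rng(children[j]).standard_normal(n) for j in range(q)]
    )
    return PhenotypeTable(values=values, trait_ids=list(trait_ids))


def permute_phenotypes(table: PhenotypeTable, seed: int) -> PhenotypeTable:
    """Independently permute each trait column, shuffling traits relative to
    each other while leaving every marginal distribution intact.

    This is the device for turning real, possibly non-normal trait columns into
    null phenotypes: any genotype-phenotype and cross-trait dependence is
    destroyed, but outliers, skewness and kurtosis are preserved column-wise.
    """
    n, q = table.values.shape
    master = np.random.SeedSequence([int(seed), _PERMUTE_STREAM])
    children = master.spawn(q)
    out = np.empty_like(table.values)
    for j in range(q):
        perm = np.random.default_rng(children[j]).permutation(n)
        out[:, j] = table.values[perm, j]
    return PhenotypeTable(values=out, trait_ids=list(table.trait_ids), subject_ids=list(table.subject_ids))


def concat_snps(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Column-concatenate two genotype matrices over the same subjects."""
    if a.n_subjects != b.n_subjects:
        raise ValueError("subject counts differ")
    return GenotypeMatrix(
        dosages=np.hstack([a.dosages, b.dosages]),
        snp_ids=list(a.snp_ids) + list(b.snp_ids),
        snp_maf=np.concatenate([a.snp_maf, b.snp_maf]),
        repeating_flags=np.concatenate([a.repeating_flags, b.repeating_flags]),
        subject_ids=list(a.subject_ids),
    )


def default_maf_spectrum(n_points: int = 2000) -> MafSpectrum:
    """A packaged empirical-style MAF spectrum spanning 0.05-0.5.

    Built deterministically with density roughly proportional to 1/p, the
    classic shape of a common-variant site-frequency spectrum after a 5% MAF
    filter; a stand-in for a cohort's observed MAF distribution when none is
    supplied.
    """
    # inverse-CDF of density ∝ 1/p on [0.05, 0.5], evaluated on a midpoint grid
    u = (np.arange(n_points) + 0.5) / n_points
    vals = 0.05 * (0.5 / 0.05) ** u
    return MafSpectrum.empirical(np.round(vals, 6))
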