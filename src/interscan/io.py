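"""File I/O: dosage-matrix / phenotype TSVs and VCF genotype import.

The native interchange format is tab-delimited text.  A genotype matrix is
written as ``<prefix>.dosages.tsv`` (header ``subject_id`` then SNP ids, one
row per subject, integer dosages, ``NA`` for missing) with a companion
``<prefix>.snps.tsv`` (snp_id, maf, repeating flag).  Phenotypes go to a
single TSV with a ``subject_id`` first column.  Every file opens with ``#``
comment lines recording the tool version, a config hash and the master seed.

VCF import is convenience-only and lossy by design: it reads the GT field,
counting the alternate allele (0/0 -> 0, 0/1 -> 1, 1/1 -> 2, any missing
allele -> missing); multi-allelic records are skipped with a count.  Minor-
allele recoding happens downstream in the scan engine, so whether the
alternate allele is minor does not matter.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import MISSING, GenotypeMatrix, PhenotypeTable

__all__ = [
    "write_genotype_matrix",
    "read_genotype_matrix",
    "write_phenotype_table",
    "read_phenotype_table",
    "read_vcf",
    "align_subjects",
    "provenance_header",
]


def _version() -> str:
    from . import __version__

    return __version__


def provenance_header(seed: int | None = None, config: dict | None = None) -> str:
    """'#'-prefixed provenance lines: tool version, config hash, master seed."""
    blob = json.dumps(config or {}, sort_keys=True, default=str)
    cfg_hash = hashlib.md5(blob.encode()).hexdigest()[:12]
    lines = [f"# interscan {_version()}", f"# config_hash {cfg_hash}"]
    if seed is not None:
        lines.append(f"# seed {seed}")
    return "\n".join(lines) + "\n"


def write_genotype_matrix(gm: GenotypeMatrix, prefix: str | Path, seed: int | None = None,
                          config: dict | None = None) -> tuple[Path, Path]:
    """Write dosages and SNP metadata; returns the two paths."""
    prefix = Path(prefix)
    dosage_path = Path(str(prefix) + ".dosages.tsv")
    meta_path = Path(str(prefix) + ".snps.tsv")
    header = provenance_header(seed, config)
    with open(dosage_path, "w") as fh:
        fh.write(header)
        fh.write("subject_id\t" + "\t".join(gm.snp_ids) + "\n")
        for i, sid in enumerate(gm.subject_ids):
            row = ["NA" if d == MISSING else str(int(d)) for d in gm.dosages[i]]
            fh.write(sid + "\t" + "\t".join(row) + "\n")
    with open(meta_path, "w") as fh:
        fh.write(header)
        fh.write("snp_id\tmaf\trepeating\n")
        for j, snp in enumerate(gm.snp_ids):
            fh.write(f"{snp}\t{gm.snp_maf[j]:.6g}\t{int(gm.repeating_flags[j])}\n")
    return dosage_path, meta_path


def read_genotype_matrix(path: str | Path, meta_path: str | Path | None = None) -> GenotypeMatrix:
    """Read a dosage TSV written by :func:`write_genotype_matrix`.

    Without a metadata sidecar, MAFs are computed from the data and no SNP is
    flagged repeating.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.columns[0] != "subject_id":
        raise ValueError(f"{path}: first column must be subject_id")
    snp_ids = list(df.columns[1:])
    subject_ids = df["subject_id"].tolist()
    raw = df.iloc[:, 1:].to_numpy()
    dosages = np.full(raw.shape, MISSING, dtype=np.int8)
    mask = (raw != "NA") & (raw != "") & pd.notna(raw)
    try:
        dosages[mask] = raw[mask].astype(np.int8)
    except ValueError as exc:
        bad = [(i + 1, snp_ids[j]) for i, j in zip(*np.where(mask)) if not str(raw[i, j]).lstrip("-").isdigit()]
        raise ValueError(f"{path}: malformed dosage values at (row, snp) {bad[:5]}") from exc
    if np.any(~np.isin(dosages, (0, 1, 2, MISSING))):
        rows, cols = np.where(~np.isin(dosages, (0, 1, 2, MISSING)))
        raise ValueError(f"{path}: dosage outside {{0,1,2,NA}} at row {rows[0] + 1}, snp {snp_ids[cols[0]]}")
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", comment="#")
        meta = meta.set_index("snp_id").loc[snp_ids]
        mafs = meta["maf"].to_numpy(dtype=float)
        flags = meta["repeating"].to_numpy(dtype=bool)
    else:
        obs = dosages != MISSING
        with np.errstate(invalid="ignore"):
            freq = np.where(obs, dosages, 0).sum(axis=0) / np.maximum(2 * obs.sum(axis=0), 1)
        mafs = np.minimum(freq, 1 - freq)
        flags = np.zeros(len(snp_ids), dtype=bool)
    return GenotypeMatrix(dosages=dosages, snp_ids=snp_ids, snp_maf=mafs,
                          repeating_flags=flags, subject_ids=subject_ids)


def write_phenotype_table(pt: PhenotypeTable, path: str | Path, seed: int | None = None,
                          config: dict | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, config))
        fh.write("subject_id\t" + "\t".join(pt.trait_ids) + "\n")
        for i, sid in enumerate(pt.subject_ids):
            fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in pt.values[i]) + "\n")
    return path


def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.columns[0] != "subject_id":
        raise ValueError(f"{path}: first column must be subject_id")
    trait_ids = list(df.columns[1:])
    if any(t.strip() == "" or t.startswith("Unnamed") for t in trait_ids):
        raise ValueError(f"{path}: empty trait column header")
    values = np.empty((len(df), len(trait_ids)))
    for j, t in enumerate(trait_ids):
        col = pd.to_numeric(df[t], errors="coerce")
        if col.isna().any():
            i = int(col.isna().idxmax())
            raise ValueError(f"{path}: non-numeric value at row {i + 1}, trait {t!r}")
        values[:, j] = col.to_numpy()
    return PhenotypeTable(values=values, trait_ids=trait_ids, subject_ids=df["subject_id"].astype(str).tolist())


def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, int]:
    """Import diploid GT fields from a VCF; returns (matrix, n_multiallelic_skipped)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    snp_ids: list[str] = []
    columns: list[np.ndarray] = []
    skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            skipped += 1
            continue
        col = np.full(len(subject_ids), MISSING, dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:
                continue
            col[i] = (a1 > 0) + (a2 > 0)
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        columns.append(col)
    vcf.close()
    if not columns:
        raise ValueError(f"{path}: no usable biallelic records")
    dosages = np.column_stack(columns)
    obs = dosages != MISSING
    freq = np.where(obs, dosages, 0).sum(axis=0) / np.maximum(2 * obs.sum(axis=0), 1)
    mafs = np.minimum(freq, 1 - freq)
    gm = GenotypeMatrix(dosages=dosages, snp_ids=snp_ids, snp_maf=mafs,
                        repeating_flags=np.zeros(len(snp_ids), dtype=bool),
                        subject_ids=subject_ids)
    return gm, skipped


def align_subjects(gm: GenotypeMatrix, pt: PhenotypeTable) -> tuple[GenotypeMatrix, PhenotypeTable, list[str]]:
    """Align phenotype rows to genotype subjects by id.

    Returns the genotype matrix restricted to shared subjects (genotype order),
    the realigned phenotype table, and the ids present in only one input.
    """
    geno_ids = list(gm.subject_ids)
    pheno_index = {s: i for i, s in enumerate(pt.subject_ids)}
    shared = [s for s in geno_ids if s in pheno_index]
    if not shared:
        raise ValueError("no overlapping subject ids between genotypes and phenotypes")
    dropped = sorted((set(geno_ids) ^ set(pt.subject_ids)))
    g_rows = [i for i, s in enumerate(geno_ids) if s in pheno_index]
    gm2 = GenotypeMatrix(
        dosages=gm.dosages[g_rows],
        snp_ids=list(gm.snp_ids),
        snp_maf=gm.snp_maf.copy(),
        repeating_flags=gm.repeating_flags.copy(),
        subject_ids=shared,
    )
    pt2 = PhenotypeTable(
        values=pt.values[[pheno_index[s] for s in shared]],
        trait_ids=list(pt.trait_ids),
        subject_ids=shared,
    )
    return gm2, pt2, dropped
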