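"""Reference genotype-class counts for nine repeating SNPs.

Published characteristics of nine common autosomal SNPs, one per MAF bin from
0.05-0.5 in steps of 0.05, genotyped in a cohort of 1,053 unrelated subjects.
Each entry holds the subject counts by minor-allele dosage (0/1/2) and the MAF
reported for the cohort (two decimals).  Used in worked examples and to
validate the minor-allele-frequency arithmetic of the scan engine against
printed values.
"""

from __future__ import annotations

__all__ = ["REPEATING_SNP_REFERENCE", "maf_from_counts"]

#: snp_id -> (n0, n1, n2, reported MAF)
REPEATING_SNP_REFERENCE: dict[str, tuple[int, int, int, float]] = {
    "rs7564315": (923, 126, 4, 0.06),
    "rs10106243": (840, 202, 11, 0.11),
    "rs6065298": (751, 280, 22, 0.15),
    "rs716982": (630, 366, 57, 0.23),
    "rs861528": (552, 430, 71, 0.27),
    "rs2408208": (451, 503, 99, 0.33),
    "rs10507467": (433, 488, 132, 0.36),
    "rs11231017": (376, 506, 171, 0.40),
    "rs998731": (295, 537, 221, 0.46),
}

#: Cohort size the counts are drawn from.
REFERENCE_COHORT_SIZE: int = 1053


def maf_from_counts(n0: int, n1: int, n2: int) -> float:
    """Minor-allele frequency from genotype-class counts: (n1 + 2*n2) / (2n)."""
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("empty genotype counts")
    freq = (n1 + 2 * n2) / (2.0 * n)
    return min(freq, 1.0 - freq)
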