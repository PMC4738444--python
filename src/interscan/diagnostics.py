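"""Heteroskedasticity and leverage diagnostics for interaction scans.

Two descriptive instruments:

* **Genotypic variance ratios** — the phenotype variance within each genotype
  class of the repeating SNP, classes ordered by size (largest = 1, smallest
  = 3), and the three pairwise variance ratios.  Ratios far from one indicate
  heteroskedasticity across genotype classes, the principal driver of
  interaction-term lambda inflation/deflation: lower variance in the largest
  class inflates lambda_3, higher variance in the largest class deflates it.

* **Leverage comparison** — the maximum hat-matrix leverage within each
  populated two-locus genotype cell under the two-locus model (II) versus the
  product-term model (III).  Adding the product column can only increase each
  observation's leverage (projection onto a larger column space), and does so
  most strongly for sparsely populated cells, which is why product-term
  inference is comparatively sensitive to assumption violations.

No formal heteroskedasticity test is offered; the ratios are descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import regression as reg
from .simulate import PhenotypeTable

__all__ = [
    "VarianceRatioReport",
    "genotypic_variance_ratios",
    "leverage_comparison",
    "heteroskedasticity_lambda_association",
    "simulate_variance_structured_phenotypes",
]


@dataclass
class VarianceRatioReport:
    """Genotype classes of the repeating SNP ordered by size (descending).

    ``class_dosages`` records which dosage each size-ordered label refers to;
    ties in class size are broken by dosage ascending.  A class with fewer than
    two subjects has no defined variance; ratios involving it are ``nan``.
    """

    class_dosages: list[int]
    class_sizes: list[int]
    class_variances: list[float]
    ratio_1_3: float
    ratio_2_3: float
    ratio_1_2: float


def genotypic_variance_ratios(x_rep, y) -> VarianceRatioReport:
    """Per-genotype-class phenotype variances of the repeating SNP and their ratios.

    Classes are the populated dosage classes (0/1/2), ordered by subject count
    descending (dosage ascending on ties); variances use the n-1 denominator.
    With two populated classes only ratio_1_2 is defined.
    """
    x = np.asarray(x_rep)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage and phenotype vectors differ in length")
    populated = [g for g in (0, 1, 2) if np.sum(x == g) > 0]
    if len(populated) < 2:
        raise ValueError("need at least two populated genotype classes")
    sizes = {g: int(np.sum(x == g)) for g in populated}
    order = sorted(populated, key=lambda g: (-sizes[g], g))
    variances = []
    for g in order:
        sel = y[x == g]
        variances.append(float(np.var(sel, ddof=1)) if sel.size >= 2 else np.nan)

    def _ratio(a: int, b: int) -> float:
        if len(order) <= max(a, b):
            return np.nan
        va, vb = variances[a], variances[b]
        if not np.isfinite(va) or not np.isfinite(vb) or vb == 0.0:
            return np.nan
        return va / vb

    return VarianceRatioReport(
        class_dosages=order,
        class_sizes=[sizes[g] for g in order],
        class_variances=variances,
        ratio_1_3=_ratio(0, 2),
        ratio_2_3=_ratio(1, 2),
        ratio_1_2=_ratio(0, 1),
    )


def leverage_comparison(x, z, y) -> dict:
    """Max leverage per populated two-locus cell under models II and III.

    Returns a dict with per-cell records and the global maxima.  The model-III
    leverages dominate the model-II leverages pointwise.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=float)
    d2 = reg.build_design("II", x, z)
    d3 = reg.build_design("III", x, z)
    h2 = reg.fit_ols(d2, y).leverage
    h3 = reg.fit_ols(d3, y).leverage
    cells = []
    for i in range(3):
        for j in range(3):
            sel = (x == i) & (z == j)
            n_cell = int(sel.sum())
            if n_cell == 0:
                continue
            cells.append(
                {
                    "cell": (i, j),
                    "n": n_cell,
                    "max_leverage_two_locus": float(h2[sel].max()),
                    "max_leverage_product": float(h3[sel].max()),
                }
            )
    return {
        "cells": cells,
        "max_leverage_two_locus": float(h2.max()),
        "max_leverage_product": float(h3.max()),
    }


def heteroskedasticity_lambda_association(lambda_values, ratio_1_3_values) -> dict:
    """Spearman rank correlation of lambda_3 with the largest/smallest-class
    variance ratio across scans, plus a sign summary.

    The expected direction: ratios below one (largest class least variable)
    accompany inflated lambda_3, ratios above one deflated lambda_3 — i.e. a
    negative rank correlation.
    """
    lam = np.asarray(lambda_values, dtype=float)
    ratio = np.asarray(ratio_1_3_values, dtype=float)
    ok = np.isfinite(lam) & np.isfinite(ratio)
    if ok.sum() < 10:
        raise ValueError("need at least 10 scans with both quantities")
    rho, p = stats.spearmanr(lam[ok], ratio[ok])
    return {
        "rank_correlation": float(rho),
        "p_value": float(p),
        "n_scans": int(ok.sum()),
        "median_lambda_ratio_below_1": float(np.median(lam[ok & (ratio < 1.0)])) if np.any(ok & (ratio < 1.0)) else np.nan,
        "median_lambda_ratio_above_1": float(np.median(lam[ok & (ratio > 1.0)])) if np.any(ok & (ratio > 1.0)) else np.nan,
    }


def simulate_variance_structured_phenotypes(
    x_rep,
    q: int,
    class_sds: tuple[float, float, float],
    seed: int,
    trait_ids: list[str] | None = None,
) -> PhenotypeTable:
    """Null phenotypes whose variance depends on the repeating SNP's genotype.

    A diagnostic stress generator (not part of the null-data simulator): each
    trait is zero-mean normal with standard deviation ``class_sds[g]`` for a
    subject of dosage g, injecting pure heteroskedasticity with no mean effect.
    Used to demonstrate the direction of the variance-ratio/lambda relationship.
    """
    x = np.asarray(x_rep)
    n = x.shape[0]
    if q < 1:
        raise ValueError("q must be at least 1")
    sds = np.asarray(class_sds, dtype=float)
    if sds.shape != (3,) or np.any(sds <= 0):
        raise ValueError("class_sds must be three positive values")
    if trait_ids is None:
        trait_ids = [f"hetero{j + 1}" for j in range(q)]
    master = np.random.SeedSequence([int(seed), 53])
    children = master.spawn(q)
    scale = sds[x]
    values = np.column_stack(
        [np.random.default_rng(children[j]).standard_normal(n) * scale for j in range(q)]
    )
    return PhenotypeTable(values=values, trait_ids=list(trait_ids))
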