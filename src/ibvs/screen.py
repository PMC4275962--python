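"""Screening-then-selection (STS) first stage: univariate SNP scans and
gene-level filtering.

Each SNP is tested marginally with a logistic regression of the outcome on
its coded genotype; a gene is significant when any of its SNPs falls below
the p-value threshold, and ALL SNPs of significant genes are retained so
the selection stage sees each candidate gene's full SNP set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import chdtrc

from .data_model import GenotypeData, Phenotype


@dataclass
class ScreenResult:
    pvalues: np.ndarray
    significant_genes: np.ndarray
    retained_snps: np.ndarray
    threshold: float


def single_snp_scan(geno, Y) -> np.ndarray:
    """Two-sided Wald p-value per SNP from univariate logistic regression.

    Constant SNP columns are excluded (p = NaN) with a warning; fits that
    fail to converge (separation) fall back to a Rao score test, flagged.
    """
    X = geno.X.astype(float) if isinstance(geno, GenotypeData) else \
        np.asarray(geno, dtype=float)
    y = Y.Y.astype(float) if isinstance(Y, Phenotype) else \
        np.asarray(Y, dtype=float)
    n, P = X.shape
    pvals = np.full(P, np.nan)
    for j in range(P):
        col = X[:, j]
        if col.std() == 0:
            warnings.warn(f"constant SNP column {j} excluded", stacklevel=2)
            continue
        design = np.column_stack([np.ones(n), col])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
                if np.abs(fit.params).max() > 30 or not fit.mle_retvals.get(
                        "converged", True):
                    raise RuntimeError("separation")
                pvals[j] = fit.pvalues[1]
            except Exception:
                # score test needs only the null model: U = x'(y - ybar)
                p0 = y.mean()
                xc = col - col.mean()
                stat = (xc @ (y - p0)) ** 2 / (p0 * (1 - p0) * (xc @ xc))
                pvals[j] = chdtrc(1, stat)
    return pvals


def gene_filter(pvals, gene_map, threshold: float = 4e-4) -> ScreenResult:
    """Retain all SNPs of every gene containing a SNP below the threshold.

    ``gene_map`` is the per-SNP gene index array (``geno.gene_of_snp``).
    """
    pvals = np.asarray(pvals, dtype=float)
    gene_map = np.asarray(gene_map)
    genes = np.unique(gene_map)
    sig = np.array([g for g in genes
                    if np.nanmin(pvals[gene_map == g], initial=np.inf)
                    < threshold], dtype=int)
    retained = np.flatnonzero(np.isin(gene_map, sig))
    return ScreenResult(pvals, sig, retained, threshold)


def subset_genotypes(geno: GenotypeData, snp_idx: np.ndarray) -> GenotypeData:
    """Reduced GenotypeData on a SNP subset (gene indices re-densified)."""
    snp_idx = np.asarray(snp_idx)
    genes_kept = np.unique(geno.gene_of_snp[snp_idx])
    remap = {int(g): j for j, g in enumerate(genes_kept)}
    return GenotypeData(
        geno.X[:, snp_idx],
        geno.sample_ids,
        [geno.snp_ids[k] for k in snp_idx],
        np.array([remap[int(g)] for g in geno.gene_of_snp[snp_idx]]),
        [geno.gene_ids[int(g)] for g in genes_kept],
        geno.coding)
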