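"""Per-gene partial-least-squares scores forming the model design matrix.

Each selected gene is summarised by the first PLS component of its selected
SNP columns against the response: the direction in SNP space whose score has
maximal covariance with the response.  The design matrix T stacks one such
score column per selected gene, ordered by gene index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import GenotypeData

logger = logging.getLogger(__name__)


@dataclass
class GeneScoreMatrix:
    """Design matrix of first-PLS gene scores.

    ``T`` is n x m with one centered column per selected gene;
    ``weights[l]`` is the unit-norm weight vector over the selected SNPs of
    gene ``column_gene[l]``; ``snp_cols[l]`` holds those SNPs' column
    indices in the full genotype matrix.
    """

    T: np.ndarray
    weights: list
    column_gene: list
    snp_cols: list

    @property
    def m(self) -> int:
        return self.T.shape[1]


def first_pls_component(X_sub: np.ndarray, response: np.ndarray):
    """First PLS direction of ``X_sub`` against ``response``.

    Columns of ``X_sub`` and the response are centered internally.  The
    weight vector is proportional to ``X_c' y_c`` normalised to unit norm;
    scores are ``X_c @ w``.  The sign is fixed so that cov(scores, response)
    is non-negative, making the component deterministic.

    Returns ``(scores, weights)`` with ``scores`` length n and ``weights``
    a unit vector of length k.
    """
    X_sub = np.asarray(X_sub, dtype=float)
    if X_sub.ndim != 2 or X_sub.shape[1] == 0:
        raise ValueError("X_sub must be n x k with k >= 1")
    y = np.asarray(response, dtype=float)
    Xc = X_sub - X_sub.mean(axis=0)
    yc = y - y.mean()
    w = Xc.T @ yc
    nrm = np.linalg.norm(w)
    if nrm == 0.0:
        # response orthogonal to every column: fall back to the first
        # principal direction so the gene still contributes a score
        logger.warning("zero PLS covariance; falling back to first PC")
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        w = Vt[0]
    else:
        w = w / nrm
    scores = Xc @ w
    if scores @ yc < 0:
        w = -w
        scores = -scores
    return scores, w


def build_design(geno: GenotypeData, xi: np.ndarray, gamma: np.ndarray,
                 response: np.ndarray, *, score_cache: dict | None = None
                 ) -> GeneScoreMatrix:
    """Assemble the gene-score design matrix for indicators ``(xi, gamma)``.

    Requires the consistency constraint: every selected gene has at least
    one selected SNP, and every selected SNP lies in a selected gene.
    Columns are ordered by ascending gene index.  ``score_cache`` maps
    ``(gene, selected-SNP tuple)`` to a cached ``(scores, weights)`` pair;
    caching never changes results because scores depend only on that key.
    """
    xi = np.asarray(xi, dtype=np.int8)
    gamma = np.asarray(gamma, dtype=np.int8)
    check_consistency(geno, xi, gamma)
    cols, weights, genes, snp_cols = [], [], [], []
    for j in np.flatnonzero(xi):
        sel = np.flatnonzero((geno.gene_of_snp == j) & (gamma == 1))
        key = (int(j), tuple(int(s) for s in sel))
        if score_cache is not None and key in score_cache:
            scores, w = score_cache[key]
        else:
            scores, w = first_pls_component(geno.X[:, sel], response)
            if score_cache is not None:
                score_cache[key] = (scores, w)
        cols.append(scores)
        weights.append(w)
        genes.append(int(j))
        snp_cols.append(sel)
    T = np.column_stack(cols) if cols else np.empty((geno.n, 0))
    return GeneScoreMatrix(T, weights, genes, snp_cols)


def check_consistency(geno: GenotypeData, xi: np.ndarray, gamma: np.ndarray
                      ) -> None:
    """Raise if (xi, gamma) violate the gene/SNP selection constraint."""
    xi = np.asarray(xi)
    gamma = np.asarray(gamma)
    if xi.shape != (geno.J,) or gamma.shape != (geno.P,):
        raise ValueError("indicator length mismatch")
    n_sel = np.bincount(geno.gene_of_snp, weights=gamma, minlength=geno.J)
    bad_empty = np.flatnonzero((xi == 1) & (n_sel == 0))
    if bad_empty.size:
        raise ValueError(
            f"gene {geno.gene_ids[bad_empty[0]]} selected with no selected SNPs")
    bad_orphan = np.flatnonzero((xi == 0) & (n_sel > 0))
    if bad_orphan.size:
        raise ValueError(
            f"gene {geno.gene_ids[bad_orphan[0]]} has selected SNPs but is "
            "not selected")
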