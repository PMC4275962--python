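"""Two-stage outcome prediction: top-i SNPs by PIP into a PLS logistic model.

SNPs are ranked by posterior inclusion probability; for each candidate
count i the top-i SNP block is reduced to its first PLS component against
the outcome and a univariate logistic regression is fitted on the score.
The number of predictors i is chosen by stratified 10-fold cross-validation
of the classification error at threshold 0.5 (first minimum under ties),
then the model is refitted on the full training set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import special
from sklearn.model_selection import StratifiedKFold

from .data_model import GenotypeData, Phenotype
from .evaluate import _irls_logistic
from .gene_summary import first_pls_component


@dataclass
class PredictionModel:
    """Fitted two-stage PLS logistic model."""

    snp_ids: list
    snp_cols: np.ndarray
    col_means: np.ndarray         # training means of the selected SNP block
    weights: np.ndarray           # unit-norm PLS direction
    intercept: float
    slope: float
    chosen_i: int
    i_grid: np.ndarray
    cv_error: np.ndarray

    def to_json(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PredictionModel":
        with open(path) as fh:
            d = json.load(fh)
        for k in ("snp_cols", "col_means", "weights", "i_grid", "cv_error"):
            d[k] = np.asarray(d[k])
        return cls(**d)


def _fit_pls_logistic(X_block: np.ndarray, y: np.ndarray):
    """First PLS score of the block + univariate logistic on the score."""
    scores, w = first_pls_component(X_block, y)
    beta, _, _ = _irls_logistic(scores[:, None], y)
    means = X_block.mean(axis=0)
    return means, w, float(beta[0]), float(beta[1])


def _apply(X_block, means, w, intercept, slope):
    score = (X_block - means) @ w
    return special.expit(intercept + slope * score)


def fit_two_stage(geno: GenotypeData, Y, pip, i_grid=None, n_folds: int = 10,
                  rng=None) -> PredictionModel:
    """Choose the top-i SNP count by CV and fit the final PLS logistic model.

    ``pip`` must cover all SNPs; ties in the PIP ranking break by SNP
    order.  ``rng`` (int seed or Generator) fixes the fold assignment.
    """
    y = Y.Y.astype(float) if isinstance(Y, Phenotype) else \
        np.asarray(Y, dtype=float)
    pip = np.asarray(pip, dtype=float)
    if pip.size != geno.P:
        raise ValueError("pip must have one entry per SNP")
    if i_grid is None:
        i_grid = np.arange(1, geno.P + 1)
    i_grid = np.asarray(sorted(set(int(i) for i in i_grid)))
    if i_grid.max() > geno.P:
        import warnings
        warnings.warn("i_grid truncated to the number of SNPs", stacklevel=2)
        i_grid = i_grid[i_grid <= geno.P]
    # stable ranking: descending PIP, ties by ascending SNP index
    order = np.argsort(-pip, kind="stable")
    if rng is None:
        seed = 0
    elif isinstance(rng, np.random.Generator):
        seed = int(rng.integers(2 ** 31))
    else:
        seed = int(rng)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(y.size), y))
    X = geno.X.astype(float)
    cv_err = np.empty(i_grid.size)
    for gi, i in enumerate(i_grid):
        cols = order[:i]
        errs = []
        for tr, te in folds:
            means, w, b0, b1 = _fit_pls_logistic(X[np.ix_(tr, cols)], y[tr])
            p = _apply(X[np.ix_(te, cols)], means, w, b0, b1)
            errs.append(np.mean((p >= 0.5).astype(float) != y[te]))
        cv_err[gi] = np.mean(errs)
    best = int(np.argmin(cv_err))  # first minimum under ties
    chosen_i = int(i_grid[best])
    cols = order[:chosen_i]
    means, w, b0, b1 = _fit_pls_logistic(X[:, cols], y)
    return PredictionModel([geno.snp_ids[k] for k in cols], cols, means, w,
                           b0, b1, chosen_i, i_grid, cv_err)


def predict_proba(model: PredictionModel, geno: GenotypeData) -> np.ndarray:
    """P(Y=1) on new samples using the stored centering and PLS weights."""
    index = {s: k for k, s in enumerate(geno.snp_ids)}
    missing = [s for s in model.snp_ids if s not in index]
    if missing:
        raise ValueError(f"test genotypes missing SNPs: {missing}")
    cols = [index[s] for s in model.snp_ids]
    X_block = geno.X[:, cols].astype(float)
    return _apply(X_block, model.col_means, model.weights,
                  model.intercept, model.slope)
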