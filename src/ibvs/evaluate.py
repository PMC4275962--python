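"""Selection-performance AUC, ROC construction, and baseline selectors.

Two AUC conventions are used depending on how a method scores SNPs:

- probability scores (posterior inclusion probabilities): the fraction of
  (causal, non-causal) pairs where the causal SNP scores strictly higher;
- path entry order (LASSO / stepwise): the fraction of pairs where the
  causal SNP enters the model strictly earlier (never-entered = +inf).

Both are Mann-Whitney statistics; under the literal formulas ties count 0
(a tie-correction counting ties as 1/2 is available via ``ties="half"``).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg, special
from sklearn.linear_model import lars_path

from .data_model import GenotypeData, Phenotype


def _auc(score_d: np.ndarray, score_c: np.ndarray, larger_wins: bool,
         ties: str) -> float:
    if score_d.size == 0 or score_c.size == 0:
        raise ValueError("causal and non-causal sets must be non-empty")
    a = score_d[:, None]
    b = score_c[None, :]
    if larger_wins:
        wins = a > b
    else:
        wins = a < b
    val = wins.mean(dtype=float)
    if ties == "half":
        val += 0.5 * (a == b).mean(dtype=float)
    return float(val)


def auc_from_probabilities(pip, truth, ties: str = "literal") -> float:
    """Pairwise AUC of probability scores over causal vs non-causal SNPs."""
    pip = np.asarray(pip, dtype=float)
    truth = np.asarray(truth, dtype=int)
    mask = np.zeros(pip.size, dtype=bool)
    mask[truth] = True
    return _auc(pip[mask], pip[~mask], larger_wins=True, ties=ties)


def auc_from_entry_order(entry_iter, truth, ties: str = "literal") -> float:
    """Pairwise AUC of path entry iterations (smaller = better, inf = never)."""
    s = np.asarray(entry_iter, dtype=float)
    truth = np.asarray(truth, dtype=int)
    mask = np.zeros(s.size, dtype=bool)
    mask[truth] = True
    return _auc(s[mask], s[~mask], larger_wins=False, ties=ties)


def run_lasso_path(geno, Y) -> np.ndarray:
    """Entry iteration of each SNP along the LARS-lasso path.

    Returns a length-P vector; SNPs whose coefficient never becomes nonzero
    get +inf.  Constant columns are dropped (warned) and get +inf.
    """
    X = geno.X.astype(float) if isinstance(geno, GenotypeData) else \
        np.asarray(geno, dtype=float)
    y = Y.Y.astype(float) if isinstance(Y, Phenotype) else \
        np.asarray(Y, dtype=float)
    P = X.shape[1]
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} constant SNP column(s) dropped",
                      stacklevel=2)
    Xk = X[:, keep] - X[:, keep].mean(axis=0)
    # integer dosage columns can be exactly collinear (perfect LD), which
    # makes LARS terminate early; a deterministic micro-jitter breaks the
    # degeneracy without affecting the entry order of informative SNPs
    jit = np.random.Generator(np.random.PCG64(0))
    Xk = Xk + 1e-7 * jit.standard_normal(Xk.shape)
    yc = y - y.mean()
    _, _, coefs = lars_path(Xk, yc, method="lasso")
    entry = np.full(Xk.shape[1], np.inf)
    nonzero = coefs != 0
    for j in range(Xk.shape[1]):
        hits = np.flatnonzero(nonzero[j])
        if hits.size:
            entry[j] = hits[0]  # path step index; step 1 = first entry
    out = np.full(P, np.inf)
    out[keep] = entry
    return out


def _irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 50,
                   tol: float = 1e-8):
    """Newton/IRLS fit of logistic regression with intercept.

    Returns (beta, XtWX, converged); raises on perfect separation signals
    (diverging coefficients).
    """
    n = X.shape[0]
    A = np.column_stack([np.ones(n), X])
    beta = np.zeros(A.shape[1])
    for _ in range(max_iter):
        eta = A @ beta
        p = special.expit(eta)
        W = p * (1 - p)
        g = A.T @ (y - p)
        H = (A * W[:, None]).T @ A
        try:
            step = linalg.solve(H, g, assume_a="pos")
        except linalg.LinAlgError:
            return beta, H, False
        beta = beta + step
        if np.abs(step).max() < tol:
            return beta, H, True
        if np.abs(beta).max() > 30:
            return beta, H, False  # separation: coefficients diverging
    return beta, H, True


def _score_test_add(X_cur: np.ndarray, y: np.ndarray, candidates: np.ndarray):
    """Rao score test p-values for adding each candidate column to the
    current logistic model (vectorised over candidates)."""
    n = y.size
    beta, _, _ = _irls_logistic(X_cur, y) if X_cur.shape[1] else \
        _irls_logistic(np.empty((n, 0)), y)
    A = np.column_stack([np.ones(n), X_cur])
    p = special.expit(A @ beta)
    W = p * (1 - p)
    resid = y - p
    U = candidates.T @ resid
    AW = A * W[:, None]
    M = linalg.solve(A.T @ AW + 1e-12 * np.eye(A.shape[1]),
                     AW.T @ candidates)
    V = np.einsum("ij,ij->j", candidates * W[:, None], candidates) - \
        np.einsum("ij,ij->j", AW @ M, candidates)
    V = np.maximum(V, 1e-300)
    stat = U ** 2 / V
    return special.chdtrc(1, stat)


def run_stepwise(geno, Y, alpha_enter: float = 0.157,
                 alpha_remove: float = 0.20, max_steps: int = 250,
                 family: str = "linear"):
    """Forward-backward stepwise regression on the binary outcome.

    Returns ``(entry_iter, final_model)`` where ``entry_iter[j]`` is the
    iteration at which SNP j first entered (+inf if never) and
    ``final_model`` is the list of SNP indices in the final model.

    ``family="linear"`` (default) is the classic sequential-F stepwise on
    the 0/1 outcome treated numerically: entry by the partial-F p-value of
    each candidate given the current model, removal by the t-test of fitted
    coefficients; the path can extend to nearly n variables, which the
    entry-order evaluation of path methods relies on.  ``family="logistic"``
    uses Rao score tests for entry and Wald tests for removal; its path
    saturates once the logistic fit separates (it stops with the
    pre-separation model, logged), leaving later markers unranked.

    The default ``alpha_enter = 0.157`` is the AIC-equivalent threshold for
    a single-parameter addition (the convention of AIC-driven stepwise
    selectors); removal is slightly looser to avoid enter/remove churn.
    """
    if family == "linear":
        return _stepwise_linear(geno, Y, alpha_enter, alpha_remove,
                                max_steps)
    X = geno.X.astype(float) if isinstance(geno, GenotypeData) else \
        np.asarray(geno, dtype=float)
    y = Y.Y.astype(float) if isinstance(Y, Phenotype) else \
        np.asarray(Y, dtype=float)
    P = X.shape[1]
    usable = X.std(axis=0) > 0
    entry = np.full(P, np.inf)
    model: list[int] = []
    it = 0
    for _ in range(max_steps):
        it += 1
        cand = [j for j in range(P) if usable[j] and j not in model]
        if not cand:
            break
        pvals = _score_test_add(X[:, model], y, X[:, cand])
        j_best = cand[int(np.argmin(pvals))]
        if pvals.min() >= alpha_enter:
            break
        model.append(j_best)
        if np.isinf(entry[j_best]):
            entry[j_best] = it
        # backward pass: drop the weakest variable if it lost significance
        beta, H, ok = _irls_logistic(X[:, model], y)
        if not ok:
            model.pop()  # separation: stop with the pre-separation model
            warnings.warn("separation in stepwise fit; stopping",
                          stacklevel=2)
            break
        if len(model) > 1:
            cov = linalg.inv(H)
            wald = beta[1:] ** 2 / np.diag(cov)[1:]
            pw = special.chdtrc(1, wald)
            worst = int(np.argmax(pw))
            if pw[worst] > alpha_remove and model[worst] != j_best:
                model.pop(worst)
    return entry, model


def _stepwise_linear(geno, Y, alpha_enter, alpha_remove, max_steps):
    """Sequential-F forward/backward stepwise on the numeric 0/1 outcome."""
    X = geno.X.astype(float) if isinstance(geno, GenotypeData) else \
        np.asarray(geno, dtype=float)
    y = Y.Y.astype(float) if isinstance(Y, Phenotype) else \
        np.asarray(Y, dtype=float)
    n, P = X.shape
    usable = X.std(axis=0) > 0
    if not usable.all():
        warnings.warn(f"{int((~usable).sum())} constant SNP column(s) "
                      "excluded", stacklevel=3)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    entry = np.full(P, np.inf)
    model: list[int] = []
    # orthonormal basis Q of the selected columns, grown incrementally
    Q = np.empty((n, 0))
    resid = yc.copy()
    it = 0
    from scipy.stats import f as f_dist, t as t_dist
    for _ in range(max_steps):
        it += 1
        in_model = np.zeros(P, dtype=bool)
        in_model[model] = True
        df_resid = n - len(model) - 2  # intercept + candidate
        if df_resid < 2:
            break
        # partial correlation of each candidate with the current residual
        Xres = Xc - Q @ (Q.T @ Xc)
        norms = np.linalg.norm(Xres, axis=0)
        ok = usable & ~in_model & (norms > 1e-8 * np.sqrt(n))
        if not ok.any():
            break
        r = np.zeros(P)
        rss = resid @ resid
        r[ok] = (Xres[:, ok].T @ resid) / (norms[ok] * np.sqrt(rss))
        F = df_resid * r ** 2 / (1 - r ** 2 + 1e-300)
        pvals = np.where(ok, f_dist.sf(F, 1, df_resid), np.inf)
        j_best = int(np.argmin(pvals))
        if pvals[j_best] >= alpha_enter:
            break
        model.append(j_best)
        if np.isinf(entry[j_best]):
            entry[j_best] = it
        qnew = Xres[:, j_best] / norms[j_best]
        Q = np.column_stack([Q, qnew])
        resid = resid - qnew * (qnew @ resid)
        # backward: drop the least significant member if it lost relevance
        if len(model) > 1:
            A = Xc[:, model]
            beta, rss_arr, rank, _ = np.linalg.lstsq(A, yc, rcond=None)
            dfr = n - len(model) - 1
            if dfr > 0 and rank == len(model):
                res_full = yc - A @ beta
                s2 = (res_full @ res_full) / dfr
                cov = s2 * np.linalg.pinv(A.T @ A)
                tstat = beta / np.sqrt(np.maximum(np.diag(cov), 1e-300))
                pw = 2 * t_dist.sf(np.abs(tstat), dfr)
                worst = int(np.argmax(pw))
                if pw[worst] > alpha_remove and model[worst] != j_best:
                    model.pop(worst)
                    # rebuild the orthonormal basis after a removal
                    Q, _ = np.linalg.qr(Xc[:, model])
                    resid = yc - Q @ (Q.T @ yc)
    return entry, model


def roc_curve(prob, Y_test, thresholds=None):
    """Sensitivity/specificity over a fixed threshold grid (0.01..0.99).

    Returns ``(thresholds, sensitivity, specificity)``; mean ROC across
    replicates can be formed pointwise per threshold.
    """
    prob = np.asarray(prob, dtype=float)
    y = Y_test.Y if isinstance(Y_test, Phenotype) else np.asarray(Y_test)
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 0.995, 0.01), 2)
    pos = y == 1
    if pos.all() or not pos.any():
        raise ValueError("Y_test must contain both classes")
    sens = np.array([(prob[pos] >= t).mean() for t in thresholds])
    spec = np.array([(prob[~pos] < t).mean() for t in thresholds])
    return thresholds, sens, spec
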