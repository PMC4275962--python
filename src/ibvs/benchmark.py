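"""Scenario-level benchmark: iBVS vs LASSO vs stepwise across replicates.

Reproduces the structure of the simulation study's selection-AUC table
(methods x scenarios, mean AUC with Monte-Carlo standard errors) and the
mean ROC curves of the prediction stage, at a configurable scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import (auc_from_entry_order, auc_from_probabilities,
                       roc_curve, run_lasso_path, run_stepwise)
from .model import Hyperparams
from .predict import fit_two_stage, predict_proba
from .sampler import ChainConfig, run_chain
from .simulate import ScenarioConfig, generate_scenario, train_test_split

METHODS = ("ibvs", "lasso", "stepwise")


@dataclass
class ScenarioResult:
    label: str
    auc: dict               # method -> per-replicate selection AUCs
    mean_auc: dict          # method -> float
    se_auc: dict            # method -> MC standard error
    roc: dict | None = None  # method -> (thresholds, mean sens, mean spec)
    prediction_auc: dict | None = None


def simulation_priors(cfg: ScenarioConfig) -> Hyperparams:
    """Priors matched to the scenario's design, following the rule that
    pi reflects the believed causal fraction of SNPs and mu the prior
    log-odds of gene relevance."""
    pi = cfg.n_causal_snps / cfg.n_snps
    p_gene = cfg.n_causal_genes / cfg.n_genes
    mu = float(np.log(p_gene / (1 - p_gene)))
    return Hyperparams(pi=pi, mu=mu, eta=0.8, c="n")


def run_scenario(label: str, *, n_replicates: int = 10,
                 n_burnin: int = 5000, n_samples: int = 25_000,
                 hp: Hyperparams | None = None, seed: int = 0,
                 with_prediction: bool = False, i_grid=None,
                 cfg_kwargs: dict | None = None) -> ScenarioResult:
    """Run all three methods on fresh replicates of one scenario.

    Each replicate's first half trains all methods; with
    ``with_prediction=True`` the held-out half is scored by the two-stage
    PLS logistic model (iBVS ranking) and by refits on the baselines'
    selected sets, and pointwise-mean ROC curves are returned.
    """
    cfg = ScenarioConfig.scenario(label, n_replicates=n_replicates,
                                  seed=seed, **(cfg_kwargs or {}))
    hp = hp or simulation_priors(cfg)
    reps = generate_scenario(cfg)
    auc = {m: [] for m in METHODS}
    roc_acc = {m: [] for m in METHODS} if with_prediction else None
    pred_auc = {m: [] for m in METHODS} if with_prediction else None
    for r, (geno, pheno, truth) in enumerate(reps):
        (tr_g, tr_y), (te_g, te_y) = train_test_split(geno, pheno)
        chain_cfg = ChainConfig(n_burnin=n_burnin, n_samples=n_samples,
                                seed=int(np.random.SeedSequence(
                                    [seed, r, 7]).generate_state(1)[0]
                                    % (2 ** 31)))
        out = run_chain(tr_g, tr_y, truth.network, hp, chain_cfg)
        auc["ibvs"].append(
            auc_from_probabilities(out.pip_snp, truth.causal_snps))
        lasso_entry = run_lasso_path(tr_g, tr_y)
        auc["lasso"].append(
            auc_from_entry_order(lasso_entry, truth.causal_snps))
        step_entry, step_model = run_stepwise(tr_g, tr_y)
        auc["stepwise"].append(
            auc_from_entry_order(step_entry, truth.causal_snps))

        if with_prediction:
            ranks = {"ibvs": out.pip_snp,
                     "lasso": -np.where(np.isfinite(lasso_entry),
                                        lasso_entry, np.inf),
                     "stepwise": -np.where(np.isfinite(step_entry),
                                           step_entry, np.inf)}
            for m in METHODS:
                model = fit_two_stage(tr_g, tr_y, ranks[m], i_grid=i_grid,
                                      rng=seed + r)
                p = predict_proba(model, te_g)
                t, sens, spec = roc_curve(p, te_y)
                roc_acc[m].append((sens, spec))
                # trapezoid AUC over the empirical ROC
                order = np.argsort(1 - spec)
                pred_auc[m].append(float(np.trapezoid(
                    sens[order], (1 - spec)[order])))
    mean_auc = {m: float(np.mean(auc[m])) for m in METHODS}
    se_auc = {m: float(np.std(auc[m], ddof=1) / np.sqrt(len(auc[m])))
              for m in METHODS}
    roc = None
    if with_prediction:
        t = np.round(np.arange(0.01, 0.995, 0.01), 2)
        roc = {m: (t, np.mean([s for s, _ in roc_acc[m]], axis=0),
                   np.mean([sp for _, sp in roc_acc[m]], axis=0))
               for m in METHODS}
        pred_auc = {m: float(np.mean(v)) for m, v in pred_auc.items()}
    return ScenarioResult(label, {m: np.array(v) for m, v in auc.items()},
                          mean_auc, se_auc, roc, pred_auc)
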