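"""Classifier scoring on simulated truth with the recall-restricted auPRC.

auPRC_R is the area under the precision-recall step curve restricted to
recall ≤ R, normalized by R so that a perfect ranking scores 1 for every R.
auPRC_1 is the standard auPRC (average precision). Genes are ranked by the
LRT p-value of the relevant test, ascending (smaller p = more positive).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .expression import observation_vector
from .fitters import fit_gene_models, fit_gene_models_averaged
from .simulator import SimulationConfig, simulate_dataset
from .testing import likelihood_ratio_test
from .trees import RegimePainting

__all__ = [
    "R_CUTOFFS",
    "auprc_r",
    "score_constrained",
    "benchmark_classifiers",
    "pooled_benchmark",
]

#: Recall cutoffs used throughout the benchmark figures.
R_CUTOFFS = (0.01, 0.05, 0.1, 0.25, 0.5, 1.0)


class EvaluationError(ValueError):
    pass


def auprc_r(scores, labels, R: float = 1.0) -> float:
    """Area under the precision-recall curve for recall ≤ R, normalized by R.

    ``scores``: higher = more positive; ``labels``: binary. The PR curve is
    the step function of cumulative precision over recall, with tied scores
    grouped into a single step (no linear PR interpolation). Requires at
    least one positive and one negative label.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise EvaluationError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("need at least one positive and one negative label")
    if not 0 < R <= 1:
        raise EvaluationError(f"R must be in (0, 1], got {R}")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    l = labels[order]
    # group boundaries of tied scores
    boundary = np.nonzero(np.diff(s))[0]
    ends = np.append(boundary, len(s) - 1)
    tp = np.cumsum(l)[ends]
    n_at = ends + 1
    precision = tp / n_at
    recall = tp / n_pos
    area = 0.0
    prev_rec = 0.0
    for rec, prec in zip(recall, precision):
        if rec <= prev_rec:
            continue
        if rec >= R:
            area += (R - prev_rec) * prec
            prev_rec = R
            break
        area += (rec - prev_rec) * prec
        prev_rec = rec
    return float(area / R)


def score_constrained(dataset, tree, averaged: bool = False) -> pd.Series:
    """Per-gene score for the constrained-vs-neutral classification:
    the BM-vs-OU1 LRT p-value (ascending = more constrained)."""
    pvals = {}
    for gene in dataset.genes:
        if averaged:
            fits = fit_gene_models_averaged(dataset, gene, tree)
        else:
            obs = observation_vector(dataset, gene, tree)
            fits = fit_gene_models(obs, tree)
        pvals[gene] = likelihood_ratio_test(fits["bm"], fits["ou1"])
    return pd.Series(pvals, name="p_constrained")


def score_adaptive(dataset, tree, painting: RegimePainting, averaged: bool = False) -> pd.Series:
    """Per-gene adaptive score: max of the two LRT p-values (vs BM, vs OU1)."""
    pvals = {}
    for gene in dataset.genes:
        if averaged:
            fits = fit_gene_models_averaged(dataset, gene, tree, painting)
        else:
            obs = observation_vector(dataset, gene, tree)
            fits = fit_gene_models(obs, tree, painting)
        pvals[gene] = max(
            likelihood_ratio_test(fits["bm"], fits["adaptive"]),
            likelihood_ratio_test(fits["ou1"], fits["adaptive"]),
        )
    return pd.Series(pvals, name="p_adaptive_max")


def benchmark_classifiers(
    positive_cfg: SimulationConfig,
    negative_cfg: SimulationConfig,
    painting: RegimePainting | None = None,
    r_cutoffs=R_CUTOFFS,
    methods=("replicate_aware", "averaged_baseline"),
) -> pd.DataFrame:
    """Simulate a positive and a negative gene pool and score both methods.

    Positives are genes simulated under ``positive_cfg`` (constrained or
    adaptive), negatives under ``negative_cfg`` (typically neutral). Both
    pools are fitted, genes are ranked by the test p-value, and auPRC_R is
    reported for every requested cutoff and method.
    """
    pos = simulate_dataset(positive_cfg, prefix="pos")
    neg = simulate_dataset(replace(negative_cfg, seed=negative_cfg.seed + 1), prefix="neg")
    tree = positive_cfg.tree
    adaptive = positive_cfg.mode == "adaptive"
    if adaptive and painting is None:
        painting = positive_cfg.painting
    rows = []
    for method in methods:
        averaged = method == "averaged_baseline"
        if adaptive:
            p_pos = score_adaptive(pos, tree, painting, averaged=averaged)
            p_neg = score_adaptive(neg, tree, painting, averaged=averaged)
        else:
            p_pos = score_constrained(pos, tree, averaged=averaged)
            p_neg = score_constrained(neg, tree, averaged=averaged)
        scores = -np.concatenate([p_pos.values, p_neg.values])
        labels = np.concatenate([np.ones(len(p_pos), int), np.zeros(len(p_neg), int)])
        for R in r_cutoffs:
            rows.append(
                {
                    "method": method,
                    "R": R,
                    "auprc_r": auprc_r(scores, labels, R),
                    "n_pos": len(p_pos),
                    "n_neg": len(p_neg),
                }
            )
    return pd.DataFrame(rows)


def pooled_benchmark(
    tree,
    alpha: float,
    sigma2: float = 10.0,
    gammas=(1.0, 1 / 2, 1 / 4, 1 / 8),
    n_genes_per_cell: int = 50,
    m_replicates: int = 4,
    seed: int = 1,
    r_cutoffs=R_CUTOFFS,
    mode: str = "constrained",
    painting: RegimePainting | None = None,
    fold: float = 2.0,
) -> pd.DataFrame:
    """Benchmark with gene pools concatenated across within-noise (γ) cells.

    Mirrors the study's aggregation: at a fixed attraction strength α, genes
    simulated at every γ passing the validity filter αγ ≤ 1/2 are pooled
    (positives and negatives alike) before ranking, then auPRC_R is computed
    on the pooled ranking for each method.
    """
    gammas = [g for g in gammas if alpha == 0 or alpha * g <= 0.5]
    if not gammas:
        raise EvaluationError("no γ cell passes the validity filter")
    pools: dict[str, list] = {m: [] for m in ("replicate_aware", "averaged_baseline")}
    labels: dict[str, list] = {m: [] for m in pools}
    for ci, g in enumerate(gammas):
        pos_cfg = SimulationConfig(
            tree=tree, mode=mode, alpha=alpha, sigma2=sigma2, gamma=g, fold=fold,
            painting=painting, m_replicates=m_replicates,
            n_genes=n_genes_per_cell, seed=seed * 1000 + 2 * ci,
        )
        neg_cfg = SimulationConfig(
            tree=tree, mode="neutral", alpha=0.0, sigma2=sigma2, gamma=g,
            m_replicates=m_replicates, n_genes=n_genes_per_cell,
            seed=seed * 1000 + 2 * ci + 1,
        )
        pos = simulate_dataset(pos_cfg, prefix=f"pos{ci}_")
        neg = simulate_dataset(neg_cfg, prefix=f"neg{ci}_")
        for method in pools:
            averaged = method == "averaged_baseline"
            if mode == "adaptive":
                p_pos = score_adaptive(pos, tree, painting, averaged=averaged)
                p_neg = score_adaptive(neg, tree, painting, averaged=averaged)
            else:
                p_pos = score_constrained(pos, tree, averaged=averaged)
                p_neg = score_constrained(neg, tree, averaged=averaged)
            pools[method].extend((-p_pos).tolist() + (-p_neg).tolist())
            labels[method].extend([1] * len(p_pos) + [0] * len(p_neg))
    rows = []
    for method in pools:
        for R in r_cutoffs:
            rows.append(
                {
                    "method": method, "alpha": alpha, "R": R,
                    "auprc_r": auprc_r(np.array(pools[method]), np.array(labels[method]), R),
                    "n_pos": int(np.sum(labels[method])),
                    "n_neg": int(len(labels[method]) - np.sum(labels[method])),
                }
            )
    return pd.DataFrame(rows)
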