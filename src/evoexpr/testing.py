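"""Likelihood-ratio tests and per-gene classification.

A gene is called *adaptive* when both the neutral (BM) and the constrained
(single-optimum OU) models are rejected in favor of the multi-regime model —
the decision uses the max of the two p-values. Otherwise it is called
*constrained* when BM is rejected in favor of the single-optimum OU, and
*neutral* when nothing is rejected.

The LRT statistic Λ = U_null − U_alt is referred to a chi-square whose
degrees of freedom equal the parameter-count difference. The α > 0 boundary
under the null makes this slightly conservative (the exact reference is a
chi-square mixture); calibration tests assert conservativeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .fitters import FitResult

__all__ = [
    "GeneClassification",
    "likelihood_ratio_test",
    "correct_pvalues",
    "classify_gene",
    "classify_genes",
]

_NESTED = {("bm", "ou1"), ("bm", "adaptive"), ("ou1", "adaptive")}


class ModelSelectionError(ValueError):
    pass


@dataclass(frozen=True)
class GeneClassification:
    gene: object
    p_constrained: float
    p_adaptive_vs_bm: float | None
    p_adaptive_vs_ou1: float | None
    p_adaptive_max: float | None
    call: str  # neutral | constrained | adaptive
    adj_p_constrained: float | None = None
    adj_p_adaptive_max: float | None = None


def likelihood_ratio_test(fit_null: FitResult, fit_alt: FitResult) -> float:
    """p-value of the LRT of a nested model pair (chi-square reference)."""
    if (fit_null.kind, fit_alt.kind) not in _NESTED:
        raise ModelSelectionError(f"models not nested: {fit_null.kind} vs {fit_alt.kind}")
    df = fit_alt.n_params - fit_null.n_params
    if df < 1:
        raise ModelSelectionError("alternative must have more parameters than the null")
    lam = fit_null.neg2_loglik - fit_alt.neg2_loglik
    if np.isnan(lam):
        raise ModelSelectionError("non-finite likelihoods; refit required")
    if lam < -1e-4:
        raise ModelSelectionError(
            f"alternative fit worse than null by {-lam:.3g}; optimizer failure, refit"
        )
    lam = max(lam, 0.0)
    return float(chi2.sf(lam, df))


def correct_pvalues(pvals, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment: BH step-up, Bonferroni, or none."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ModelSelectionError("p-values must lie in [0, 1]")
    method = method.lower()
    if method == "none":
        return p.copy()
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1] if p.size else p.copy()
    if method == "bonferroni":
        return multipletests(p, method="bonferroni")[1] if p.size else p.copy()
    raise ModelSelectionError(f"unknown correction method {method!r}")


def classify_gene(
    fits: dict[str, FitResult],
    alpha_level: float = 0.05,
    gene=None,
) -> GeneClassification:
    """Classify one gene from its fitted models (no cross-gene correction).

    ``fits`` must contain "bm" and "ou1"; "adaptive" is optional. For
    cross-gene FDR control use :func:`classify_genes`.
    """
    for k in ("bm", "ou1"):
        if k not in fits:
            raise ModelSelectionError(f"missing {k} fit")
    p_con = likelihood_ratio_test(fits["bm"], fits["ou1"])
    p_ab = p_ao = p_max = None
    if "adaptive" in fits:
        p_ab = likelihood_ratio_test(fits["bm"], fits["adaptive"])
        p_ao = likelihood_ratio_test(fits["ou1"], fits["adaptive"])
        p_max = max(p_ab, p_ao)
    if p_max is not None and p_max < alpha_level:
        call = "adaptive"
    elif p_con < alpha_level:
        call = "constrained"
    else:
        call = "neutral"
    return GeneClassification(gene, p_con, p_ab, p_ao, p_max, call)


def classify_genes(
    gene_fits: dict[object, dict[str, FitResult]],
    alpha_level: float = 0.05,
    correction: str = "BH",
) -> pd.DataFrame:
    """Classify a gene set with multiple-testing correction per test family.

    The constrained-test p-values and the adaptive max-p values are adjusted
    separately (each family across all genes), then the adaptive-first
    decision rule is applied at ``alpha_level`` on the adjusted values.
    """
    genes = list(gene_fits)
    raw = [classify_gene(gene_fits[g], alpha_level, gene=g) for g in genes]
    adj_con = correct_pvalues([c.p_constrained for c in raw], correction)
    has_adaptive = all(c.p_adaptive_max is not None for c in raw) and raw
    adj_max = (
        correct_pvalues([c.p_adaptive_max for c in raw], correction)
        if has_adaptive
        else [None] * len(raw)
    )
    rows = []
    for c, ac, am in zip(raw, adj_con, adj_max):
        if am is not None and am < alpha_level:
            call = "adaptive"
        elif ac < alpha_level:
            call = "constrained"
        else:
            call = "neutral"
        rows.append(
            {
                "gene": c.gene,
                "p_constrained": c.p_constrained,
                "p_adaptive_vs_bm": c.p_adaptive_vs_bm,
                "p_adaptive_vs_ou1": c.p_adaptive_vs_ou1,
                "p_adaptive_max": c.p_adaptive_max,
                "adj_p_constrained": float(ac),
                "adj_p_adaptive_max": None if am is None else float(am),
                "call": call,
            }
        )
    return pd.DataFrame(rows)
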