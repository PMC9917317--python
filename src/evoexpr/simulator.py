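"""Exact simulation of replicated expression evolution on a tree.

Trait values evolve from the root by exact OU (or BM) transition sampling
along each branch: over a branch of length Δ in regime r,

    X_child ~ N(X_parent e^{−αΔ} + θ_r (1 − e^{−αΔ}),  σ²(1 − e^{−2αΔ})/2α),

reducing to N(X_parent, σ²Δ) at α = 0. Each species then yields M replicate
observations y_{i,k} = X_i + N(0, γσ²).

The default grids are the simulation-study conditions: root expression 1000,
σ² ∈ {1,2,5,10,20,50,100}, γ ∈ {1,...,1/64}, α ∈ {1/8,...,32},
fold ∈ {0.5,...,2}, with the validity filter αγ ≤ 1/2 (within-species
variance not exceeding the asymptotic between-species variance σ²/2α).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, LONG_COLUMNS, ObservationVector
from .trees import PhyloTree, RegimePainting

__all__ = [
    "ROOT_EXPRESSION",
    "SIGMA2_GRID",
    "GAMMA_GRID",
    "ALPHA_GRID",
    "FOLD_GRID",
    "SimulationConfig",
    "simulate_gene",
    "simulate_dataset",
    "simulate_grid",
]

ROOT_EXPRESSION = 1000.0
SIGMA2_GRID = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0)
GAMMA_GRID = (1.0, 1 / 2, 1 / 4, 1 / 8, 1 / 16, 1 / 32, 1 / 64)
ALPHA_GRID = (1 / 8, 1 / 4, 1 / 2, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
FOLD_GRID = (0.5, 0.8, 0.9, 0.95, 1.05, 1.1, 1.25, 2.0)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation condition.

    ``mode`` is neutral (α=0 BM), constrained (single optimum; defaults to
    the root value, override with ``theta={"theta0": ...}``), or adaptive
    (two-plus regimes; the shifted regimes' optima are fold × background
    optimum, or give ``theta`` per regime name). The process starts at the
    root expression for neutral/constrained and at the background regime's
    optimum for adaptive.
    """

    tree: PhyloTree
    mode: str  # neutral | constrained | adaptive
    sigma2: float
    gamma: float
    alpha: float = 0.0
    root: float = ROOT_EXPRESSION
    fold: float = 1.0
    painting: RegimePainting | None = None
    theta: dict[str, float] | None = None
    m_replicates: int = 4
    n_genes: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("neutral", "constrained", "adaptive"):
            raise SimulationError(f"unknown mode {self.mode!r}")
        if self.mode == "neutral" and self.alpha != 0:
            raise SimulationError("neutral mode requires alpha = 0")
        if self.mode != "neutral" and not self.alpha > 0:
            raise SimulationError(f"{self.mode} mode requires alpha > 0")
        if self.sigma2 < 0 or self.gamma < 0:
            raise SimulationError("sigma2 and gamma must be nonnegative")
        if self.mode == "adaptive":
            if self.painting is None or self.painting.n_regimes < 2:
                raise SimulationError("adaptive mode needs a >=2-regime painting")
            if not self.fold > 0:
                raise SimulationError("fold must be positive")

    @property
    def within_species_valid(self) -> bool:
        """Validity filter αγ ≤ 1/2 (within-species variance γσ² does not
        exceed the asymptotic between-species variance σ²/2α)."""
        if self.alpha == 0:
            return True
        return self.alpha * self.gamma <= 0.5

    def regime_optima(self) -> dict[str, float] | None:
        if self.mode != "adaptive":
            return None
        if self.theta is not None:
            return dict(self.theta)
        names = self.painting.regime_names
        background = names[self.painting.root_regime]
        return {n: self.root if n == background else self.root * self.fold for n in names}

    def root_state(self) -> float:
        if self.mode == "adaptive":
            return self.regime_optima()[self.painting.regime_names[self.painting.root_regime]]
        return self.root


def _gene_rng(seed: int, gene_index: int) -> np.random.Generator:
    # counter-based substream: same dataset regardless of generation order
    return np.random.default_rng([seed, gene_index])


def simulate_gene(cfg: SimulationConfig, rng: np.random.Generator) -> ObservationVector:
    """Simulate one gene; returns the canonical flattened observation vector."""
    tree = cfg.tree
    optima = cfg.regime_optima()
    x = np.empty(tree.n_nodes)
    x[0] = cfg.root_state()
    # one standard-normal draw per branch in preorder, consumed recursively so
    # ancestral deviations propagate (decayed by e^{-alpha dt}) to descendants
    eps = rng.standard_normal(tree.n_nodes - 1)
    for node in range(1, tree.n_nodes):
        dt = tree.branch_length[node]
        parent_x = x[tree.parent[node]]
        if cfg.alpha > 0:
            decay = np.exp(-cfg.alpha * dt)
            var = cfg.sigma2 * (-np.expm1(-2.0 * cfg.alpha * dt)) / (2.0 * cfg.alpha)
            if cfg.mode == "adaptive":
                theta_r = optima[cfg.painting.regime_names[int(cfg.painting.branch_regime[node])]]
            elif cfg.theta:
                theta_r = cfg.theta["theta0"]
            else:
                theta_r = cfg.root
            x[node] = parent_x * decay + theta_r * (1.0 - decay) + np.sqrt(var) * eps[node - 1]
        else:
            x[node] = parent_x + np.sqrt(cfg.sigma2 * dt) * eps[node - 1]
    tip_x = x[tree.tips]
    M = cfg.m_replicates
    noise_sd = np.sqrt(cfg.gamma * cfg.sigma2)
    reps = tip_x[:, None] + rng.standard_normal((tree.n_tips, M)) * noise_sd
    y = reps.reshape(-1)
    species_index = np.repeat(np.arange(tree.n_tips), M)
    pairs = [(sp, str(k + 1)) for sp in tree.tip_labels for k in range(M)]
    return ObservationVector(y, species_index, pairs)


def simulate_dataset(cfg: SimulationConfig, prefix: str = "g") -> ExpressionMatrix:
    """Simulate ``cfg.n_genes`` genes into a long-format expression matrix.

    Per-gene RNG substreams are derived from (seed, gene index), so the
    dataset is reproducible and order-independent.
    """
    records = []
    for g in range(cfg.n_genes):
        obs = simulate_gene(cfg, _gene_rng(cfg.seed, g))
        gene = f"{prefix}{g:05d}"
        for (sp, rep), val in zip(obs.pairs, obs.y):
            records.append((gene, sp, rep, val))
    return ExpressionMatrix(pd.DataFrame(records, columns=LONG_COLUMNS))


def simulate_grid(
    base_cfg: SimulationConfig,
    alphas=None,
    sigma2s=None,
    gammas=None,
    folds=None,
    trees: dict[str, PhyloTree] | None = None,
    m_replicates=None,
    apply_validity_filter: bool = False,
):
    """Cartesian product of simulation conditions (the study grids by default).

    Yields ``(cell, cfg)`` pairs where ``cell`` is a dict of the varied
    values plus the ``valid`` flag (αγ ≤ 1/2). With
    ``apply_validity_filter=True`` invalid cells are dropped rather than
    flagged. Datasets are generated lazily by the caller via
    :func:`simulate_dataset`.
    """
    if base_cfg.mode == "neutral":
        alphas = [0.0]
    elif alphas is None:
        alphas = ALPHA_GRID
    sigma2s = SIGMA2_GRID if sigma2s is None else sigma2s
    gammas = GAMMA_GRID if gammas is None else gammas
    if base_cfg.mode != "adaptive":
        folds = [1.0]
    elif folds is None:
        folds = FOLD_GRID
    trees = {"tree": base_cfg.tree} if trees is None else trees
    m_replicates = [base_cfg.m_replicates] if m_replicates is None else m_replicates
    combos = list(itertools.product(alphas, sigma2s, gammas, folds, trees.items(), m_replicates))
    if not combos:
        raise SimulationError("empty simulation grid")
    for a, s2, g, fold, (tname, tree), m in combos:
        cfg = replace(base_cfg, alpha=a, sigma2=s2, gamma=g, fold=fold, tree=tree, m_replicates=m)
        cell = {
            "alpha": a, "sigma2": s2, "gamma": g, "fold": fold,
            "tree": tname, "m_replicates": m, "valid": cfg.within_species_valid,
        }
        if apply_validity_filter and not cfg.within_species_valid:
            continue
        yield cell, cfg
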