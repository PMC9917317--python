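from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import evoexpr as ev
from evoexpr.simulator import _gene_rng, simulate_gene

TOY_NEWICK = "((A:1.0,B:1.0):1.0,C:2.0);"


@pytest.fixture(scope="session")
def toy_tree():
    return ev.read_newick(TOY_NEWICK)


@pytest.fixture(scope="session")
def dros9():
    return ev.nine_taxon_tree()


@pytest.fixture(scope="session")
def two_regime_painting(dros9):
    return ev.paint_clades(dros9, ev.two_subgenus_clades(), background="sophophora")


@pytest.fixture(scope="session")
def toy_c_painting(toy_tree):
    """Two regimes on the toy tree: the branch to C is the shifted regime."""
    assign = {
        lab: ("shift" if lab == "C" else "base")
        for lab in toy_tree.labels[1:]
    }
    # base must be named first so it is the root regime
    ordered = {lab: r for lab, r in sorted(assign.items(), key=lambda kv: kv[1])}
    return ev.paint_regimes(toy_tree, ordered)


def make_matrix(rows):
    """rows: (gene, species, replicate, value) tuples."""
    return ev.expression_from_frame(
        pd.DataFrame(rows, columns=["gene", "species", "replicate", "value"])
    )


def simulate_gene_group(tree, mode, alpha, n_genes, seed, sigma2=4.0, gamma=1 / 16,
                        m_replicates=4, root_mean=10.0, root_sd=2.0):
    """Gene group with gene-specific baselines (log-scale traits).

    Each gene draws its own root value (= optimum for the constrained mode)
    from N(root_mean, root_sd^2), emulating the spread of baseline expression
    across a real gene set; used for divergence-kinetics checks.
    """
    rng = np.random.default_rng(seed)
    roots = rng.normal(root_mean, root_sd, n_genes)
    base = ev.SimulationConfig(
        tree=tree, mode=mode, alpha=alpha, sigma2=sigma2, gamma=gamma,
        m_replicates=m_replicates, n_genes=1, seed=seed,
    )
    rows = []
    for g in range(n_genes):
        obs = simulate_gene(replace(base, root=float(roots[g])), _gene_rng(seed, g))
        for (sp, rep), val in zip(obs.pairs, obs.y):
            rows.append((f"g{g:04d}", sp, rep, val))
    return make_matrix(rows)
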