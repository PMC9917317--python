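import numpy as np
import pandas as pd
import pytest

import evoexpr as ev
from evoexpr.expression import averaged_matrix
from evoexpr.fitters import fit_gene_models_averaged

from conftest import make_matrix


def constant_obs(tree, c=5.0, m=2):
    n = tree.n_tips
    y = np.full(n * m, c)
    idx = np.repeat(np.arange(n), m)
    pairs = [(sp, str(k)) for sp in tree.tip_labels for k in range(m)]
    return ev.ObservationVector(y, idx, pairs)


@pytest.fixture(scope="module")
def mixed_dataset(dros9, two_regime_painting):
    """Small mixed-mode dataset for nesting and invariance checks."""
    frames = []
    for i, (mode, alpha, fold) in enumerate(
        [("neutral", 0.0, 1.0), ("constrained", 2.0, 1.0), ("adaptive", 4.0, 2.0)]
    ):
        cfg = ev.SimulationConfig(
            tree=dros9, mode=mode, alpha=alpha, sigma2=10.0, gamma=0.25, fold=fold,
            painting=two_regime_painting if mode == "adaptive" else None,
            m_replicates=4, n_genes=4, seed=40 + i,
        )
        mat = ev.simulate_dataset(cfg, prefix=f"{mode}_")
        frames.append(mat.data)
    return ev.expression_from_frame(pd.concat(frames, ignore_index=True))


class TestNesting:
    def test_nested_optima_chain(self, dros9, two_regime_painting, mixed_dataset):
        # BM ⊂ OU1 ⊂ adaptive: optimal -2logL must be nonincreasing
        for gene in mixed_dataset.genes:
            obs = ev.observation_vector(mixed_dataset, gene, dros9)
            fits = ev.fit_gene_models(obs, dros9, two_regime_painting)
            assert fits["bm"].neg2_loglik >= fits["ou1"].neg2_loglik - 1e-6
            assert fits["ou1"].neg2_loglik >= fits["adaptive"].neg2_loglik - 1e-6

    def test_parameter_counts(self, dros9, two_regime_painting, mixed_dataset):
        gene = mixed_dataset.genes[0]
        obs = ev.observation_vector(mixed_dataset, gene, dros9)
        fits = ev.fit_gene_models(obs, dros9, two_regime_painting)
        assert fits["bm"].n_params == 3
        assert fits["ou1"].n_params == 4
        assert fits["adaptive"].n_params == 5


class TestDegenerateAndCollapse:
    def test_constant_data_bm(self, toy_tree):
        f = ev.fit_bm(constant_obs(toy_tree, c=7.0), toy_tree)
        assert f.degenerate and f.theta["theta0"] == 7.0 and f.sigma2 == 0.0

    def test_constant_data_ou1(self, toy_tree):
        f = ev.fit_ou_constrained(constant_obs(toy_tree, c=7.0), toy_tree)
        assert f.theta["theta0"] == 7.0

    def test_single_replicate_fixes_gamma(self, toy_tree):
        rng = np.random.default_rng(0)
        obs = ev.ObservationVector(rng.normal(5, 1, 3), np.arange(3),
                                   [("A", "1"), ("B", "1"), ("C", "1")])
        f = ev.fit_bm(obs, toy_tree)
        assert f.gamma == 0.0 and f.n_params == 2

    def test_averaged_baseline_equals_fit_on_means(self, dros9, mixed_dataset):
        gene = mixed_dataset.genes[0]
        base = ev.fit_averaged_baseline(mixed_dataset, gene, dros9, kind="bm")
        avg = averaged_matrix(mixed_dataset)
        direct = ev.fit_bm(ev.observation_vector(avg, gene, dros9), dros9)
        assert base.neg2_loglik == pytest.approx(direct.neg2_loglik, abs=1e-10)
        assert base.gamma == 0.0

    def test_averaging_then_fitting_differs_from_replicate_aware(self, toy_tree):
        mat = make_matrix([
            ("g", "A", "1", 1.0), ("g", "A", "2", 9.0),
            ("g", "B", "1", 4.0), ("g", "B", "2", 6.0),
            ("g", "C", "1", 2.0), ("g", "C", "2", 8.0),
        ])
        replicate_aware = ev.fit_bm(ev.observation_vector(mat, "g", toy_tree), toy_tree)
        baseline = ev.fit_averaged_baseline(mat, "g", toy_tree, kind="bm")
        # same species means but very different within-species spread: the
        # replicate-aware fit sees it, the averaged baseline cannot
        assert replicate_aware.sigma2 != pytest.approx(baseline.sigma2, rel=1e-3)


class TestInvariances:
    def test_replicate_relabeling(self, dros9, mixed_dataset):
        gene = mixed_dataset.genes[1]
        df = mixed_dataset.data[mixed_dataset.data["gene"] == gene].copy()
        relabeled = df.assign(replicate=df["replicate"].map({"1": "d", "2": "c", "3": "b", "4": "a"}))
        a = ev.fit_ou_constrained(
            ev.observation_vector(ev.expression_from_frame(df), gene, dros9), dros9)
        b = ev.fit_ou_constrained(
            ev.observation_vector(ev.expression_from_frame(relabeled), gene, dros9), dros9)
        assert a.neg2_loglik == pytest.approx(b.neg2_loglik, abs=1e-8)
        assert a.alpha == pytest.approx(b.alpha, rel=1e-6)

    def test_tip_order_permutation(self, mixed_dataset):
        # same topology written with rotated clades: fits must be identical
        t1 = ev.nine_taxon_tree()
        rotated = (
            "((dgri:0.5,(dmoj:0.25,dvir:0.25):0.25):0.5,"
            "((dwil:0.55,(dper:0.1,dpse:0.1):0.45):0.25,"
            "(dana:0.45,(dyak:0.22,dmel:0.22):0.23):0.35):0.2);"
        )
        t2 = ev.read_newick(rotated)
        gene = mixed_dataset.genes[2]
        a = ev.fit_bm(ev.observation_vector(mixed_dataset, gene, t1), t1)
        b = ev.fit_bm(ev.observation_vector(mixed_dataset, gene, t2), t2)
        assert a.neg2_loglik == pytest.approx(b.neg2_loglik, abs=1e-8)
        assert a.sigma2 == pytest.approx(b.sigma2, rel=1e-6)


class TestAdaptive:
    def test_single_optimum_data_gives_equal_optima(self, dros9, two_regime_painting):
        cfg = ev.SimulationConfig(
            tree=dros9, mode="constrained", alpha=8.0, sigma2=10.0, gamma=0.125,
            m_replicates=4, n_genes=20, seed=9,
        )
        mat = ev.simulate_dataset(cfg)
        ratios = []
        for gene in mat.genes:
            obs = ev.observation_vector(mat, gene, dros9)
            f = ev.fit_ou_adaptive(obs, dros9, two_regime_painting)
            ratios.append(f.theta["drosophila"] / f.theta["sophophora"])
        assert np.median(ratios) == pytest.approx(1.0, abs=0.05)

    def test_needs_two_regimes(self, toy_tree):
        p = ev.single_regime(toy_tree)
        with pytest.raises(Exception, match="2 regimes"):
            ev.fit_ou_adaptive(constant_obs(toy_tree), toy_tree, p)

    def test_theta_names_follow_painting(self, dros9, two_regime_painting, mixed_dataset):
        gene = mixed_dataset.genes[0]
        obs = ev.observation_vector(mixed_dataset, gene, dros9)
        f = ev.fit_ou_adaptive(obs, dros9, two_regime_painting)
        assert set(f.theta) == {"sophophora", "drosophila"}

    def test_alpha_gamma_flag(self):
        f = ev.FitResult("ou1", 4.0, 1.0, 0.5, {"theta0": 0.0}, 0.0, 4, True, 1)
        assert f.alpha_gamma_exceeds_half
        g = ev.FitResult("ou1", 0.5, 1.0, 0.5, {"theta0": 0.0}, 0.0, 4, True, 1)
        assert not g.alpha_gamma_exceeds_half


def test_baseline_smoke_all_kinds(dros9, two_regime_painting, mixed_dataset):
    gene = mixed_dataset.genes[-1]
    fits = fit_gene_models_averaged(mixed_dataset, gene, dros9, two_regime_painting)
    assert fits["bm"].neg2_loglik >= fits["ou1"].neg2_loglik - 1e-6
    assert fits["ou1"].neg2_loglik >= fits["adaptive"].neg2_loglik - 1e-6
    assert all(f.gamma == 0.0 for f in fits.values())
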