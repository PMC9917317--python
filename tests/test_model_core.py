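import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal

import evoexpr as ev
from evoexpr.model_core import ModelError

IDX1 = np.array([0, 1, 2])  # one observation per toy-tree tip
IDX2 = np.repeat([0, 1, 2], 2)  # two replicates per tip


@pytest.fixture(scope="module")
def toy(toy_tree):
    return {
        "tree": toy_tree,
        "epochs": ev.lineage_epochs(toy_tree),
        "s": ev.shared_time_matrix(toy_tree),
    }


class TestWeightMatrix:
    def test_single_regime_is_all_ones(self, toy, toy_tree):
        p = ev.single_regime(toy_tree)
        for alpha in (0.1, 1.0, 17.3):
            W = ev.ou_weight_matrix(toy["epochs"], p, alpha, IDX2)
            assert np.allclose(W.values, 1.0)

    def test_two_regime_values(self, toy, toy_c_painting):
        # regime "shift" covers only the branch to C; at alpha = 0.5 the C row
        # is (e^-1, 1 - e^-1) and the A, B rows are (1, 0)
        W = ev.ou_weight_matrix(toy["epochs"], toy_c_painting, 0.5, IDX1)
        i_base = W.regime_names.index("base")
        i_shift = W.regime_names.index("shift")
        assert W.values[0, i_base] == pytest.approx(1.0)
        assert W.values[0, i_shift] == pytest.approx(0.0)
        assert W.values[2, i_base] == pytest.approx(np.exp(-1.0), abs=1e-10)
        assert W.values[2, i_shift] == pytest.approx(1 - np.exp(-1.0), abs=1e-10)

    def test_large_alpha_limit_is_terminal_regime_indicator(self, toy, toy_c_painting):
        W = ev.ou_weight_matrix(toy["epochs"], toy_c_painting, 50.0, IDX1)
        expected = np.zeros((3, 2))
        expected[0, W.regime_names.index("base")] = 1
        expected[1, W.regime_names.index("base")] = 1
        expected[2, W.regime_names.index("shift")] = 1
        assert np.allclose(W.values, expected, atol=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=100.0))
    def test_rows_sum_to_one(self, toy_tree, toy_c_painting, alpha):
        ep = ev.lineage_epochs(toy_tree)
        W = ev.ou_weight_matrix(ep, toy_c_painting, alpha, IDX2)
        assert np.allclose(W.values.sum(axis=1), 1.0, atol=1e-12)

    def test_replicate_rows_identical(self, toy, toy_c_painting):
        W = ev.ou_weight_matrix(toy["epochs"], toy_c_painting, 0.7, IDX2)
        assert np.array_equal(W.values[0], W.values[1])

    def test_unmerged_root_column(self, toy, toy_c_painting):
        W = ev.ou_weight_matrix(toy["epochs"], toy_c_painting, 0.5, IDX1, merge_root=False)
        assert W.values.shape[1] == 3
        assert np.allclose(W.values[:, 0], np.exp(-0.5 * 2.0))
        assert np.allclose(W.values.sum(axis=1), 1.0)

    def test_nonpositive_alpha_errors(self, toy, toy_c_painting):
        with pytest.raises(ModelError):
            ev.ou_weight_matrix(toy["epochs"], toy_c_painting, 0.0, IDX1)


class TestScaledCovariance:
    def test_ou_entries(self, toy):
        C = ev.ou_scaled_covariance(toy["s"], 0.5, IDX1)
        assert C.values[0, 1] == pytest.approx(np.exp(-1) * (1 - np.exp(-1)), abs=1e-10)
        assert C.values[0, 0] == pytest.approx(1 - np.exp(-2), abs=1e-10)
        assert C.values[0, 2] == 0.0

    def test_bm_limit(self, toy):
        C = ev.ou_scaled_covariance(toy["s"], 1e-8, IDX2)
        S = ev.bm_scaled_covariance(toy["s"], IDX2)
        assert np.max(np.abs(C.values - S.values)) < 1e-6

    def test_replicates_share_species_entry(self, toy):
        C = ev.ou_scaled_covariance(toy["s"], 0.8, IDX2)
        assert C.values[0, 1] == pytest.approx(C.values[0, 0])  # (A,1)-(A,2) vs diag

    def test_bm_block_expansion(self, toy):
        S = ev.bm_scaled_covariance(toy["s"], IDX2)
        base = np.array([[2, 1, 0], [1, 2, 0], [0, 0, 2]], dtype=float)
        assert np.allclose(S.values, np.kron(base, np.ones((2, 2))))

    def test_single_species_constant_block(self):
        t = ev.read_newick("(A:1.5);")
        s = ev.shared_time_matrix(t)
        S = ev.bm_scaled_covariance(s, np.zeros(3, dtype=int))
        assert np.allclose(S.values, 1.5)

    def test_singular_without_gamma_when_replicated(self, toy):
        C = ev.ou_scaled_covariance(toy["s"], 1.0, IDX2)
        with pytest.raises(ModelError, match="positive definite"):
            ev.profile_sigma_theta(np.arange(6.0), np.ones((6, 1)), C, 0.0)


class TestProfile:
    def test_zero_residual(self, toy):
        C = ev.ou_scaled_covariance(toy["s"], 1.0, IDX2)
        s2, th = ev.profile_sigma_theta(np.full(6, 3.3), np.ones((6, 1)), C, 0.5)
        assert th[0] == pytest.approx(3.3)
        assert s2 == pytest.approx(0.0, abs=1e-20)

    def test_pure_noise_limit_is_ols(self):
        y = np.array([1.0, 2.0, 4.0, 5.0])
        C = np.zeros((4, 4))
        s2a, tha = ev.profile_sigma_theta(y, np.ones((4, 1)), C, 1.0)
        s2b, thb = ev.profile_sigma_theta(y, np.ones((4, 1)), C, 2.0)
        assert tha[0] == pytest.approx(y.mean())
        assert thb[0] == pytest.approx(y.mean())
        assert s2a == pytest.approx(2 * s2b)  # sigma2-hat scales as 1/gamma

    def test_beats_grid_search(self, toy):
        # closed form must minimize U over (sigma2, theta): compare against a
        # 50x50 lattice around the closed-form optimum
        rng = np.random.default_rng(4)
        C = ev.ou_scaled_covariance(toy["s"], 0.7, IDX2)
        W = np.ones((6, 1))
        for _ in range(5):
            y = rng.normal(10, 3, 6)
            s2, th = ev.profile_sigma_theta(y, W, C, 0.3)
            u_star = ev.neg2_loglik_full(y, W, C, s2, 0.3, th)
            grid_s2 = np.linspace(0.25 * s2, 4 * s2, 50)
            grid_th = np.linspace(th[0] - 3, th[0] + 3, 50)
            u_grid = min(
                ev.neg2_loglik_full(y, W, C, a, 0.3, np.array([b]))
                for a in grid_s2 for b in grid_th
            )
            assert u_star <= u_grid + 1e-6


class TestLikelihood:
    def test_standard_normal_at_mean(self):
        u = ev.neg2_loglik_full(
            np.array([2.0]), np.ones((1, 1)), np.array([[1.0]]), 1.0, 0.0, np.array([2.0])
        )
        assert u == pytest.approx(np.log(2 * np.pi))

    def test_matches_mvn_oracle(self, toy):
        rng = np.random.default_rng(7)
        C = ev.ou_scaled_covariance(toy["s"], 1.3, IDX2)
        W = np.ones((6, 1))
        y = rng.normal(0, 2, 6)
        u = ev.neg2_loglik_full(y, W, C, 2.5, 0.4, np.array([1.0]))
        V = 2.5 * (C.values + 0.4 * np.eye(6))
        assert u == pytest.approx(-2 * multivariate_normal.logpdf(y, np.ones(6), V), abs=1e-8)

    def test_profile_equals_full_at_optimum(self, toy, toy_c_painting):
        rng = np.random.default_rng(11)
        y = rng.normal(5, 1, 6)
        C = ev.ou_scaled_covariance(toy["s"], 1.0, IDX2)
        W = ev.ou_weight_matrix(toy["epochs"], toy_c_painting, 1.0, IDX2)
        u, s2, th = ev.neg2_loglik_profile(y, W, C, 0.5)
        assert u == pytest.approx(ev.neg2_loglik_full(y, W, C, s2, 0.5, th), abs=1e-8)

    def test_tree_automorphism_symmetry(self, toy, toy_c_painting):
        # swapping the exchangeable tips A and B (with their data) leaves U unchanged
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y_swap = np.array([3.0, 4.0, 1.0, 2.0, 5.0, 6.0])
        C = ev.ou_scaled_covariance(toy["s"], 0.9, IDX2)
        W = ev.ou_weight_matrix(toy["epochs"], toy_c_painting, 0.9, IDX2)
        u1, *_ = ev.neg2_loglik_profile(y, W, C, 0.3)
        u2, *_ = ev.neg2_loglik_profile(y_swap, W, C, 0.3)
        assert u1 == pytest.approx(u2, abs=1e-10)
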