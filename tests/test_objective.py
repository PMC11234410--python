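import numpy as np
import pytest

from batchfree.corrector import correct_cells, init_corrector
from batchfree.critic import critic_score, init_critics
from batchfree.objective import (
    ObjectiveConfig,
    gradient_penalty,
    interpolate,
    pair_coefficient,
    total_objective,
    wasserstein_term,
)
from .test_critic import linear_critic


class TestPairCoefficient:
    @pytest.mark.parametrize("i,j,M,expected", [
        (2, 2, 5, 1.0),
        (0, 1, 3, -0.5),
        (0, 1, 2, -1.0),
        (4, 0, 5, -0.25),
    ])
    def test_values(self, i, j, M, expected):
        assert pair_coefficient(i, j, M) == pytest.approx(expected)

    @pytest.mark.parametrize("M", range(2, 11))
    def test_rows_sum_to_zero(self, M):
        for i in range(M):
            total = sum(pair_coefficient(i, j, M) for j in range(M))
            assert total == pytest.approx(0.0, abs=1e-12)

    def test_small_M_rejected(self):
        with pytest.raises(ValueError):
            pair_coefficient(0, 0, 1)


class TestInterpolate:
    def test_endpoints_and_equal_rows(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([[2.0, 4.0], [1.0, 1.0]])

        class T0:
            def uniform(self, lo, hi, size):
                return np.zeros(size)

        class T1:
            def uniform(self, lo, hi, size):
                return np.ones(size)

        np.testing.assert_array_equal(interpolate(x, y, T0()), x)
        np.testing.assert_array_equal(interpolate(x, y, T1()), y)
        same = interpolate(x, x, np.random.default_rng(0))
        np.testing.assert_allclose(same, x)

    def test_quarter_point(self):
        class T25:
            def uniform(self, lo, hi, size):
                return np.full(size, 0.25)

        out = interpolate(np.array([[0.0, 0.0]]), np.array([[2.0, 4.0]]), T25())
        np.testing.assert_allclose(out, [[0.5, 1.0]])

    def test_rows_stay_on_segment(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 3))
        y = rng.normal(size=(20, 3))
        s = interpolate(x, y, rng)
        assert np.all(s >= np.minimum(x, y) - 1e-12)
        assert np.all(s <= np.maximum(x, y) + 1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            interpolate(np.ones((2, 3)), np.ones((3, 3)), np.random.default_rng(0))


class TestGradientPenalty:
    def test_unit_norm_linear_critic_zero_penalty(self):
        ens = linear_critic(np.array([0.6, 0.8]))  # ||w|| = 1
        s = np.abs(np.random.default_rng(2).normal(size=(10, 2)))
        assert gradient_penalty(ens, 0, s) == pytest.approx(0.0, abs=1e-12)

    def test_zero_critic_penalty_one(self):
        ens = init_critics(3, (4, 4), 2, seed=0)
        for k in ens.critics[0]:
            ens.critics[0][k][:] = 0.0
        assert gradient_penalty(ens, 0, np.ones((5, 3))) == pytest.approx(1.0)

    def test_norm_three_penalty_four(self):
        ens = linear_critic(np.array([3.0, 0.0]))
        s = np.abs(np.random.default_rng(3).normal(size=(7, 2)))
        assert gradient_penalty(ens, 0, s) == pytest.approx(4.0)

    def test_empty_input_rejected(self):
        ens = init_critics(2, (3, 3), 2, seed=0)
        with pytest.raises(ValueError):
            gradient_penalty(ens, 0, np.empty((0, 2)))


class TestWassersteinTerm:
    def test_zero_critic_gives_zero(self):
        ens = init_critics(2, (3, 3), 2, seed=0)
        for k in ens.critics[0]:
            ens.critics[0][k][:] = 0.0
        mbs = [np.ones((4, 2)), np.ones((3, 2))]
        assert wasserstein_term(ens, 0, mbs) == pytest.approx(0.0)

    def test_two_batch_identity_critic_mean_difference(self):
        ens = linear_critic(np.array([1.0]))
        mbs = [np.full((4, 1), 5.0), np.full((6, 1), 2.0)]
        assert wasserstein_term(ens, 0, mbs) == pytest.approx(3.0)

    def test_balanced_means_cancel_for_three_batches(self):
        ens = init_critics(2, (3, 3), 3, seed=1)
        for j in range(3):
            ens.critics[j]["v3"] = np.random.default_rng(j).normal(size=(3, 1))
        mb = np.abs(np.random.default_rng(4).normal(size=(5, 2)))
        mbs = [mb, mb.copy(), mb.copy()]  # identical batches -> every term cancels
        for j in range(3):
            assert wasserstein_term(ens, j, mbs) == pytest.approx(0.0, abs=1e-12)

    def test_empty_minibatch_rejected(self):
        ens = init_critics(2, (3, 3), 2, seed=0)
        with pytest.raises(ValueError):
            wasserstein_term(ens, 0, [np.ones((2, 2)), np.empty((0, 2))])


class TestTotalObjective:
    def _setup(self, M, p=3, seed=0):
        rng = np.random.default_rng(seed)
        ens = init_critics(p, (4, 3), M, seed=seed)
        for j in range(M):
            ens.critics[j]["v3"] = np.random.default_rng(seed + j).normal(size=(3, 1))
        corr = init_corrector(p, (4, 4), M, seed=seed + 100)
        mbs = [np.abs(rng.normal(size=(6, p))) for _ in range(M)]
        return ens, corr, mbs

    def test_zero_critics_zero_lambda_total_zero(self):
        ens, corr, mbs = self._setup(2)
        for c in ens.critics:
            for k in c:
                c[k][:] = 0.0
        cfg = ObjectiveConfig(lambda_gp=0.0)
        lb = total_objective(ens, corr, mbs, cfg, np.random.default_rng(0))
        assert lb.total == pytest.approx(0.0)

    def test_two_batch_reduction_matches_direct_form(self):
        # with lambda = 0 the total collapses to the two-batch data terms
        ens, corr, mbs = self._setup(2, seed=3)
        cfg = ObjectiveConfig(lambda_gp=0.0)
        lb = total_objective(ens, corr, mbs, cfg, np.random.default_rng(1))
        c0 = correct_cells(mbs[0], 0, corr).corrected
        c1 = correct_cells(mbs[1], 1, corr).corrected
        direct = (
            np.mean(critic_score(ens, 0, c0)) - np.mean(critic_score(ens, 0, c1))
            + np.mean(critic_score(ens, 1, c1)) - np.mean(critic_score(ens, 1, c0))
        )
        assert lb.total == pytest.approx(direct, rel=1e-10)

    def test_breakdown_identity(self):
        ens, corr, mbs = self._setup(3, seed=5)
        cfg = ObjectiveConfig(lambda_gp=10.0)
        lb = total_objective(ens, corr, mbs, cfg, np.random.default_rng(2))
        recomputed = float(np.sum(lb.per_critic_wasserstein) + cfg.lambda_gp * lb.penalty_total)
        assert lb.total == pytest.approx(recomputed, rel=1e-12)

    def test_batch_relabeling_symmetry(self):
        # permuting batches together with their critics permutes the per-critic
        # terms and leaves the data part of the loss unchanged
        ens, corr, mbs = self._setup(3, seed=8)
        cfg = ObjectiveConfig(lambda_gp=0.0)
        lb = total_objective(ens, corr, mbs, cfg, np.random.default_rng(3))
        perm = [2, 0, 1]
        ens_p = ens.copy()
        ens_p.critics = [ens.critics[i] for i in perm]
        corr_p = corr.copy()
        corr_p.params["bs_scale"] = corr.params["bs_scale"][perm]
        corr_p.params["bs_bias"] = corr.params["bs_bias"][perm]
        mbs_p = [mbs[i] for i in perm]
        lb_p = total_objective(ens_p, corr_p, mbs_p, cfg, np.random.default_rng(3))
        np.testing.assert_allclose(
            lb_p.per_critic_wasserstein, lb.per_critic_wasserstein[perm], rtol=1e-12)
        assert lb_p.total == pytest.approx(lb.total, rel=1e-12)
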