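import numpy as np
import pytest

from ratequity import (
    SubgroupEstimates,
    hierarchical_shrinkage_oracle,
    identity_weights,
    optimal_weights,
    rate_estimate,
    shared_weights,
)
from ratequity.fixtures import MTO_PHI, mto_summary_rows
from ratequity.data import from_summaries

from conftest import random_estimates


class TestOptimalWeights:
    def test_rows_are_probability_vectors(self, mto_estimates):
        Q = optimal_weights(mto_estimates, MTO_PHI)
        assert Q.Q.sum(axis=1) == pytest.approx(np.ones(4), abs=1e-12)
        assert (Q.Q >= 0).all() and (Q.Q <= 1).all()

    @pytest.mark.parametrize("diagonal", [True, False])
    def test_row_stochastic_on_random_instances(self, diagonal):
        rng = np.random.default_rng(5)
        for _ in range(25):
            est = random_estimates(rng, int(rng.integers(2, 7)), diagonal=diagonal)
            Q = optimal_weights(est, float(rng.random() * 2 + 1e-3))
            assert Q.Q.sum(axis=1) == pytest.approx(np.ones(est.n_groups), abs=1e-10)

    def test_large_phi_gives_identity(self, mto_estimates):
        """As phi -> infinity the adjustment vanishes (fully stratified)."""
        Q = optimal_weights(mto_estimates, 1e6)
        assert np.abs(Q.Q - np.eye(4)).max() < 1e-6

    def test_equal_variance_closed_form(self):
        """Equal diagonal variances: q_g = w e_g + (1-w)/G with
        w = phi^2/(2 sigma^2 + phi^2); phi^2 = 2 sigma^2, G=4 gives self-weight
        0.625 and off-diagonals 0.125."""
        sigma_sq = 0.3
        phi = np.sqrt(2 * sigma_sq)
        est = SubgroupEstimates([f"g{i}" for i in range(4)], np.zeros(4),
                                sigma_sq * np.eye(4), p=np.full(4, 0.25))
        Q = optimal_weights(est, phi).Q
        expected = 0.125 * np.ones((4, 4)) + 0.5 * np.eye(4)
        assert Q == pytest.approx(expected, abs=1e-12)

    def test_phi_zero_limit_is_gls_pooling(self):
        """phi = 0 pools fully: every row equals the inverse-variance weights,
        the analytic limit of the weight formula as phi drops to 0."""
        rng = np.random.default_rng(9)
        est = random_estimates(rng, 4, diagonal=True)
        Q0 = optimal_weights(est, 0.0).Q
        iv = 1 / np.diag(est.cov)
        iv /= iv.sum()
        assert Q0 == pytest.approx(np.tile(iv, (4, 1)), abs=1e-12)
        # continuity: tiny phi approaches the limit
        Qeps = optimal_weights(est, 1e-7).Q
        assert np.abs(Qeps - Q0).max() < 1e-6

    def test_self_weight_nondecreasing_in_phi(self):
        rng = np.random.default_rng(11)
        est = random_estimates(rng, 5, diagonal=True)
        phis = [0.0, 0.05, 0.2, 0.5, 1.0, 3.0, 10.0]
        selfw = np.array([np.diag(optimal_weights(est, ph).Q) for ph in phis])
        assert (np.diff(selfw, axis=0) >= -1e-12).all()

    def test_vanishing_standard_errors_give_identity(self, mto_estimates):
        """As all SEs shrink, the data dominate and Q -> I (asymptotic unbiasedness)."""
        prev = np.inf
        for k in (2, 4, 6, 8):
            est = SubgroupEstimates(mto_estimates.labels, mto_estimates.tau_hat,
                                    mto_estimates.cov * 10.0**-k, p=mto_estimates.p)
            dev = np.abs(optimal_weights(est, MTO_PHI).Q - np.eye(4)).max()
            assert dev < prev
            prev = dev
        assert prev < 1e-6

    def test_correlated_estimators_can_leave_unit_interval(self):
        """Strong negative correlation can push generalized weights outside
        [0,1]; they are returned unclipped with a warning and still sum to 1."""
        cov = np.array([[0.1401, -0.1039, 0.0486],
                        [-0.1039, 0.1477, 0.0057],
                        [0.0486, 0.0057, 0.0878]])
        est = SubgroupEstimates(["a", "b", "c"], [0.1, 0.2, 0.0], cov,
                                p=np.full(3, 1 / 3))
        with pytest.warns(UserWarning, match="generalized"):
            Q = optimal_weights(est, 0.317)
        assert Q.Q.sum(axis=1) == pytest.approx(np.ones(3), abs=1e-10)
        assert (Q.Q < 0).any() or (Q.Q > 1).any()


class TestSharedWeights:
    def test_equal_variance_closed_form(self):
        """sigma^2 = 1 I, G = 3, phi^2 = 2: gamma = 1/2, self-weight 2/3,
        off-diagonals 1/6."""
        est = SubgroupEstimates(["a", "b", "c"], np.zeros(3), np.eye(3),
                                p=np.full(3, 1 / 3))
        Q = shared_weights(est, np.sqrt(2.0))
        assert Q.diagnostics["gamma"] == pytest.approx(0.5)
        assert np.diag(Q.Q) == pytest.approx(np.full(3, 2 / 3))
        assert Q.Q[0, 1] == pytest.approx(1 / 6)

    def test_large_phi_gives_identity(self, mto_estimates):
        Q = shared_weights(mto_estimates, 1e6)
        assert np.abs(Q.Q - np.eye(4)).max() < 1e-6

    def test_single_shared_self_weight(self, mto_estimates):
        """All rows share one self-weight and rows sum to 1 on the MTO inputs."""
        Q = shared_weights(mto_estimates, MTO_PHI)
        d = np.diag(Q.Q)
        assert np.ptp(d) < 1e-12
        assert Q.Q.sum(axis=1) == pytest.approx(np.ones(4), abs=1e-12)
        off = Q.Q[~np.eye(4, dtype=bool)]
        assert np.ptp(off) < 1e-12

    def test_gamma_nonnegative_for_valid_covariances(self):
        """For PSD covariances, off-diagonal mass cannot exceed (G-1) sigma-bar^2,
        so gamma >= 0 and the self-weight stays in [0, 1]."""
        rng = np.random.default_rng(21)
        for _ in range(40):
            est = random_estimates(rng, int(rng.integers(2, 7)), diagonal=False)
            Q = shared_weights(est, float(rng.random() * 2 + 0.05))
            assert Q.diagnostics["gamma"] >= 0
            assert 0 <= Q.diagnostics["w"] <= 1

    def test_negative_gamma_clamped_to_identity(self):
        """Defensive clamp: a degenerate covariance (only reachable past the PSD
        validation) with off-diagonal mass above sigma-bar^2 (G-1) yields
        gamma < 0, which is clamped to identity weights with a warning."""
        est = SubgroupEstimates(["a", "b"], [0.0, 0.0], np.diag([0.01, 0.01]),
                                p=[0.5, 0.5])
        est.cov = np.array([[0.01, 0.05], [0.05, 0.01]])  # bypasses validation
        with pytest.warns(UserWarning, match="clamping"):
            Q = shared_weights(est, 0.3)
        assert np.allclose(Q.Q, np.eye(2))

    def test_regularity_violation_raises(self):
        """The gamma denominator must be positive; a degenerate covariance with
        phi too small violates the regularity condition."""
        est = SubgroupEstimates(["a", "b"], [0.0, 0.0], np.diag([0.01, 0.01]),
                                p=[0.5, 0.5])
        est.cov = np.array([[0.01, 0.05], [0.05, 0.01]])
        with pytest.raises(ValueError, match="regularity"):
            shared_weights(est, 0.1)

    def test_self_weight_nondecreasing_in_phi(self, mto_estimates):
        phis = [0.05, 0.125, 0.25, 0.5, 2.0]
        w = [shared_weights(mto_estimates, ph).diagnostics["w"] for ph in phis]
        assert (np.diff(w) > 0).all()


class TestShrinkageOracle:
    def test_infinite_phi_returns_estimates(self):
        tau = np.array([0.3, -0.2, 0.9])
        out = hierarchical_shrinkage_oracle(tau, np.array([0.1, 0.2, 0.3]), np.inf)
        assert out == pytest.approx(tau)

    def test_phi_zero_full_pooling(self):
        tau = np.array([1.0, 3.0])
        se_sq = np.array([1.0, 1.0])
        out = hierarchical_shrinkage_oracle(tau, se_sq, 0.0)
        assert out == pytest.approx([2.0, 2.0])

    def test_matches_optimal_rate_in_diagonal_case(self):
        """Algebraic identity: with uncorrelated estimators the optimal-weights
        adjusted estimates equal the hierarchical-shrinkage posterior means."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            G = int(rng.integers(2, 8))
            est = random_estimates(rng, G, diagonal=True)
            phi = float(rng.random() * 3 + 1e-4)
            eta = rate_estimate(est, optimal_weights(est, phi)).eta
            oracle = hierarchical_shrinkage_oracle(est.tau_hat, np.diag(est.cov), phi)
            assert np.abs(eta - oracle).max() < 1e-10


class TestWeightMatrixContainer:
    def test_identity_weights(self, mto_estimates):
        Q = identity_weights(mto_estimates)
        assert np.allclose(Q.Q, np.eye(4))

    def test_non_stochastic_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            from ratequity.weights import WeightMatrix
            WeightMatrix(np.array([[0.5, 0.4], [0.5, 0.5]]), ["a", "b"], 1.0, "custom")

    def test_csv_roundtrip(self, tmp_path, mto_estimates):
        from ratequity.weights import WeightMatrix
        Q = optimal_weights(mto_estimates, MTO_PHI)
        path = tmp_path / "q.csv"
        Q.to_csv(path)
        back = WeightMatrix.from_csv(path)
        assert back.Q == pytest.approx(Q.Q, abs=1e-12)
        assert back.labels == Q.labels
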