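"""Bayesian-regularized Levenberg-Marquardt training of the 3-3-1 network."""

import numpy as np
import pytest

from radqsar.ann import (
    AnnArchitecture,
    AnnTrainConfig,
    BayesianRegularizedMLP,
    TrainedAnn,
    _AffineMap,
    _forward_scaled,
    ann_report,
    bayesian_update,
    forward,
    jacobian,
    lm_step,
    train_ann,
)
from radqsar.errors import AlignmentError, RadqsarError


def identity_maps(d):
    return _AffineMap(lo=np.full(d, -1.0), span=np.full(d, 2.0))


def make_net(arch, weights):
    return TrainedAnn(architecture=arch, weights=np.asarray(weights, float),
                      descriptor_ids=tuple(f"x{i}" for i in range(arch.n_input)),
                      input_scaling=identity_maps(arch.n_input),
                      output_scaling=identity_maps(1),
                      alpha=0.0, beta=1.0, gamma=0.0, epochs_run=0)


class TestForward:
    def test_zero_weights_predict_output_bias(self, rng):
        net = make_net(AnnArchitecture(), np.zeros(16))
        X = rng.normal(size=(5, 3))
        np.testing.assert_allclose(forward(net, X), 0.0, atol=1e-15)

    def test_hand_evaluated_1_1_1_network(self):
        arch = AnnArchitecture(n_input=1, n_hidden=1)
        w1, b1, w2, b2 = 0.8, -0.1, 1.5, 0.3
        net = make_net(arch, [w1, b1, w2, b2])
        x = 0.4
        expected = w2 * np.tanh(w1 * x + b1) + b2
        assert forward(net, [[x]])[0] == pytest.approx(expected, rel=1e-12)

    def test_forward_is_smooth(self, rng):
        net = make_net(AnnArchitecture(), rng.uniform(-1, 1, 16))
        X = rng.normal(size=(4, 3))
        delta = np.abs(forward(net, X + 1e-9) - forward(net, X))
        assert delta.max() < 1e-6

    def test_column_mismatch_rejected(self, rng):
        net = make_net(AnnArchitecture(), np.zeros(16))
        with pytest.raises(AlignmentError):
            forward(net, rng.normal(size=(3, 2)))

    def test_weight_count_invariant(self):
        assert AnnArchitecture().n_weights == 16


class TestJacobian:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_central_differences(self, seed):
        rng = np.random.default_rng(seed)
        arch = AnnArchitecture()
        w = rng.uniform(-1, 1, arch.n_weights)
        Xs = rng.uniform(-1, 1, (6, 3))
        J = jacobian(arch, w, Xs)
        h = 1e-6
        for k in range(arch.n_weights):
            wp, wm = w.copy(), w.copy()
            wp[k] += h
            wm[k] -= h
            fd = (_forward_scaled(arch, wp, Xs)[0]
                  - _forward_scaled(arch, wm, Xs)[0]) / (2 * h)
            np.testing.assert_allclose(J[:, k], fd, rtol=1e-6, atol=1e-8)

    def test_zero_input_row_reflects_only_bias_paths(self):
        arch = AnnArchitecture()
        rng = np.random.default_rng(0)
        w = rng.uniform(-1, 1, arch.n_weights)
        J = jacobian(arch, w, np.zeros((1, 3)))
        # input-weight derivatives vanish at x = 0 (dyhat/dW1_jk = ... * x_k)
        np.testing.assert_allclose(J[0, :9], 0.0, atol=1e-15)
        assert np.abs(J[0, 9:12]).min() > 0  # hidden-bias paths alive


class TestLmStep:
    def test_large_damping_freezes_weights(self, rng):
        w = rng.normal(size=4)
        J = rng.normal(size=(10, 4))
        r = rng.normal(size=10)
        step = lm_step(w, J, r, mu=1e14) - w
        assert np.abs(step).max() < 1e-10

    def test_single_undamped_step_solves_linear_least_squares(self, rng):
        """With alpha=0 and a linear residual, one LM step = OLS optimum."""
        A = rng.normal(size=(20, 4))
        b = rng.normal(size=20)
        w0 = rng.normal(size=4)
        r0 = A @ w0 - b
        w1 = lm_step(w0, A, r0, mu=1e-12, alpha=0.0, beta=1.0)
        w_ols, *_ = np.linalg.lstsq(A, b, rcond=None)
        np.testing.assert_allclose(w1, w_ols, rtol=1e-6, atol=1e-8)

    def test_objective_monotone_when_hyperparameters_fixed(self, rng):
        X = rng.uniform(-1, 1, (20, 3))
        y = np.tanh(X).sum(axis=1)
        m = BayesianRegularizedMLP(bayesian=False, rng_seed=0,
                                   max_epochs=100).fit(X, y)
        hist = m.objective_history_
        assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))


class TestBayesianUpdate:
    def test_shrinkage_pressure_direction(self):
        JtJ = np.eye(16)
        a1, _, _ = bayesian_update(0.5, 1.0, E_W=1e-4, E_D=1.0, n_obs=50,
                                   n_weights=16, JtJ=JtJ)
        a2, _, _ = bayesian_update(0.5, 1.0, E_W=1.0, E_D=1.0, n_obs=50,
                                   n_weights=16, JtJ=JtJ)
        assert a1 > a2  # tiny E_W with many effective params -> strong prior

    def test_gamma_clamped_below_observation_count(self):
        _, _, g = bayesian_update(1e-9, 1.0, E_W=1.0, E_D=1.0, n_obs=12,
                                  n_weights=16, JtJ=np.eye(16))
        assert 0.0 <= g <= 11.0

    def test_requires_positive_energies(self):
        with pytest.raises(RadqsarError):
            bayesian_update(0.1, 1.0, E_W=0.0, E_D=1.0, n_obs=10,
                            n_weights=16, JtJ=np.eye(16))

    def test_pure_noise_target_few_effective_parameters(self, rng):
        Xn = rng.uniform(-1, 1, (12, 3))
        yn = rng.normal(0, 1, 12)
        m = BayesianRegularizedMLP(rng_seed=0).fit(Xn, yn)
        assert m.gamma_ < 16 / 2

    def test_smooth_signal_uses_many_effective_parameters(self, rng):
        X = rng.uniform(-1, 1, (100, 3))
        y = np.tanh(2 * X) @ [1.0, 0.8, 0.6] + rng.normal(0, 0.01, 100)
        m = BayesianRegularizedMLP(rng_seed=0).fit(X, y)
        assert m.gamma_ > 16 / 2


class TestTraining:
    def test_noise_free_linear_target_fits_to_tolerance(self, rng):
        X = rng.uniform(-1, 1, (50, 3))
        y = X.sum(axis=1)
        m = BayesianRegularizedMLP(rng_seed=0).fit(X, y)
        rmse = float(np.sqrt(((m.predict(X) - y) ** 2).mean()))
        assert rmse <= 1e-3

    def test_fixed_seed_bit_identical(self, ref_split):
        _, train, _ = ref_split
        cfg = AnnTrainConfig(rng_seed=11)
        n1 = train_ann(train, "Y1", ("X17", "X19", "X20"), cfg)
        n2 = train_ann(train, "Y1", ("X17", "X19", "X20"), cfg)
        assert np.array_equal(n1.weights, n2.weights)
        assert n1.alpha == n2.alpha and n1.gamma == n2.gamma

    def test_nonlinear_target_reaches_noise_floor(self, rng):
        sigma = 0.2
        X = rng.uniform(-1, 1, (100, 3))
        y = 2.0 * np.tanh(2 * X) @ [1.0, 0.7, 0.5] + rng.normal(0, sigma, 100)
        m = BayesianRegularizedMLP(rng_seed=0).fit(X, y)
        rmse = float(np.sqrt(((m.predict(X) - y) ** 2).mean()))
        assert 0.8 * sigma <= rmse <= 1.3 * sigma

    def test_regularization_suppresses_overfitting(self, rng):
        Xn = rng.uniform(-1, 1, (12, 3))
        yn = rng.normal(0, 1, 12)

        def train_r2(**kw):
            m = BayesianRegularizedMLP(rng_seed=2, **kw).fit(Xn, yn)
            p = m.predict(Xn)
            return 1 - ((p - yn) ** 2).sum() / ((yn - yn.mean()) ** 2).sum()

        assert train_r2() < train_r2(bayesian=False) - 0.2

    def test_wrong_descriptor_count_rejected(self, ref_split):
        _, train, _ = ref_split
        with pytest.raises(RadqsarError):
            train_ann(train, "Y1", ("X17", "X19"))


class TestAnnReport:
    def test_perfect_and_mean_predictions(self, ref_split):
        _, train, test = ref_split
        net = train_ann(train, "Y1", ("X17", "X19", "X20"),
                        AnnTrainConfig(rng_seed=1))
        train_stats, test_stats = ann_report(net, train, test, "Y1")
        assert 0.0 < train_stats.r2 <= 1.5  # ESS/TSS definition, non-OLS fit
        assert train_stats.rmse >= 0.0 and test_stats.n == 3

    def test_noise_ceiling_on_planted_signal(self, rng):
        """Train R^2 tracks the population signal share 1 - sigma^2/var(y)."""
        sigma = 0.3
        X = rng.uniform(-1, 1, (200, 3))
        signal = 2.0 * np.tanh(2 * X) @ [1.0, 0.7, 0.5]
        y = signal + rng.normal(0, sigma, 200)
        m = BayesianRegularizedMLP(rng_seed=0).fit(X, y)
        p = m.predict(X)
        r2 = 1 - ((p - y) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        ceiling = 1 - sigma ** 2 / y.var()
        assert r2 == pytest.approx(ceiling, abs=0.05)
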