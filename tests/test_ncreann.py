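"""Order selection, network fitting, linear/nonlinear connectivity, surrogates."""

import dataclasses

import numpy as np
import pytest

from thetanet.ncreann import (
    NMVARNet,
    TrainConfig,
    evaluate_model,
    extract_linear_part,
    fit_ncreann,
    lagged_design,
    linear_connectivity,
    nonlinear_connectivity,
    nonlinear_connectivity_retrain,
    select_order_sbc,
    surrogate_test,
)
from thetanet.synthetic import (
    LinearVARSpec,
    NLTerm,
    NonlinearVARSpec,
    gen_linear_var,
    gen_nonlinear_var,
)
from ._oracles import lyapunov_cov, r_squared


def _random_net(M=2, p=2, H=6, seed=0, scale=0.5):
    rng = np.random.default_rng(seed)
    return NMVARNet(
        M=M, p=p,
        W1=rng.uniform(-scale, scale, (H, M * p)),
        b1=rng.uniform(-scale, scale, H),
        W2=rng.uniform(-scale, scale, (M, H)),
        b2=rng.uniform(-scale, scale, M),
    )


class TestOrderSelection:
    def test_recovers_var3_order(self):
        A = np.zeros((3, 3, 3))
        A[0] = [[0.4, 0.2, 0.0], [0.0, 0.3, 0.2], [0.2, 0.0, 0.3]]
        A[1] = [[-0.3, 0.0, 0.1], [0.1, -0.2, 0.0], [0.0, 0.1, -0.2]]
        A[2] = [[0.2, 0.1, 0.0], [0.0, 0.2, 0.1], [0.1, 0.0, 0.2]]
        spec = LinearVARSpec(M=3, p_true=3, A=A, n_samples=5000, seed=0)
        data = gen_linear_var(spec)[0].data[:, :, 0]
        assert select_order_sbc(data, 6) == 3

    def test_white_noise_selects_minimum_order(self):
        rng = np.random.default_rng(1)
        assert select_order_sbc(rng.standard_normal((3, 2000)), 6) == 1

    def test_too_large_order_for_series_length_errors(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="at least n ="):
            select_order_sbc(rng.standard_normal((3, 50)), 20)

    def test_nonfinite_series_rejected(self):
        bad = np.zeros((2, 100))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            select_order_sbc(bad, 2)


class TestFitting:
    def test_constant_channel_rejected(self, fast_train):
        data = np.vstack([np.ones(500), np.random.default_rng(0).standard_normal(500)])
        with pytest.raises(ValueError, match="zero variance"):
            fit_ncreann(data, 1, fast_train)

    def test_fit_is_seed_deterministic(self, var2_data, fast_train):
        data, _ = var2_data
        a = fit_ncreann(data[:, :1500], 1, fast_train)
        b = fit_ncreann(data[:, :1500], 1, fast_train)
        assert np.array_equal(linear_connectivity(a), linear_connectivity(b))
        assert a.fold_metrics == b.fold_metrics

    def test_r2_reaches_theoretical_share_and_generalizes(self, var2_data):
        # theoretical maximum R^2 per channel follows from the
        # innovation-to-signal variance ratio of the generating VAR(1)
        data, _ = var2_data
        A1 = np.array([[0.5, 0.0], [0.4, 0.5]])
        G0 = lyapunov_cov(A1, np.eye(2))
        r2_max = float(np.mean(1.0 - 1.0 / np.diag(G0)))
        fit = fit_ncreann(data, 1, TrainConfig(seed=5))
        r2_test = fit.mean_metric("r2_test")
        r2_train = fit.mean_metric("r2_train")
        assert r2_test >= 0.5 * r2_max
        assert abs(r2_train - r2_test) < 0.1  # similar values = generalization

    def test_fold_count_and_metrics_shape(self, var2_fit):
        assert len(var2_fit.nets) == 2
        for m in var2_fit.fold_metrics:
            assert {"mse_train", "mse_test", "r2_train", "r2_test"} <= set(m)


class TestEvaluation:
    def test_perfect_predictor_scores_zero_error_unit_r2(self):
        net = _random_net(seed=3)
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 4))
        Y = net.predict(X)
        mse, r2 = evaluate_model(net, X, Y)
        assert mse == pytest.approx(0.0, abs=1e-24)
        assert r2 == pytest.approx(1.0)

    def test_mean_only_predictor_scores_zero_r2(self):
        net = _random_net(seed=1)
        net.W2[:] = 0.0  # constant output b2
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 4))
        Y = rng.standard_normal((200, 2)) + net.b2  # mean approx b2
        Y -= Y.mean(axis=0) - net.b2  # force exact mean
        _, r2 = evaluate_model(net, X, Y)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_r2_matches_independent_formula_on_small_fixture(self):
        net = _random_net(seed=4)
        rng = np.random.default_rng(5)
        X = rng.standard_normal((10, 4))
        Y = rng.standard_normal((10, 2))
        _, r2 = evaluate_model(net, X, Y)
        pred = net.predict(X)
        oracle = np.mean([r_squared(Y[:, j], pred[:, j]) for j in range(2)])
        assert r2 == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_target_rejected(self):
        net = _random_net()
        X = np.zeros((10, 4))
        Y = np.ones((10, 2))
        with pytest.raises(ValueError, match="zero-variance"):
            evaluate_model(net, X, Y)


class TestLinearPart:
    def test_extracted_map_equals_numerical_jacobian_at_origin(self):
        net = _random_net(M=3, p=2, seed=7)
        L = net.linear_map()
        h = 1e-5
        D = net.M * net.p
        jac = np.empty_like(L)
        for d in range(D):
            e = np.zeros((1, D))
            e[0, d] = h
            jac[:, d] = ((net.predict(e) - net.predict(-e)) / (2 * h))[0]
        assert np.max(np.abs(jac - L)) / np.max(np.abs(L)) < 1e-6

    def test_zero_output_weights_give_zero_linear_map(self):
        net = _random_net(seed=2)
        net.W2[:] = 0.0
        assert np.allclose(extract_linear_part(net), 0.0)

    def test_lag_tensor_shape_and_indexing(self):
        net = _random_net(M=3, p=4, seed=1)
        A = extract_linear_part(net)
        assert A.shape == (4, 3, 3)
        L = net.linear_map()
        assert np.allclose(A[2], L[:, 6:9])

    def test_flin_plus_fnonlin_reconstructs_f_to_first_order(self):
        net = _random_net(seed=9)
        x = np.full((1, 4), 1e-6)
        full = net.predict(x)
        lin = net.predict_linear(x)
        assert np.allclose(full, lin, atol=1e-10)


class TestLinearConnectivity:
    def test_zero_network_gives_zero_connectivity(self):
        net = _random_net(seed=0)
        net.W2[:] = 0.0
        assert np.allclose(linear_connectivity(net), 0.0)

    def test_lag_and_weight_routes_agree_exactly(self):
        net = _random_net(M=3, p=3, seed=11)
        a = linear_connectivity(net, route="lags")
        b = linear_connectivity(net, route="weights")
        assert np.max(np.abs(a - b)) < 1e-12

    @pytest.mark.parametrize("aggregate", ["l1", "max", "l2"])
    def test_aggregation_modes_nonnegative(self, aggregate):
        net = _random_net(M=2, p=3, seed=3)
        assert np.all(linear_connectivity(net, aggregate=aggregate) >= 0)

    def test_recovers_directed_edge_on_fitted_net(self, var2_fit):
        lC = linear_connectivity(var2_fit)
        assert lC[0, 1] > lC[1, 0]  # generator edge is 0 -> 1

    def test_permutation_equivariance(self):
        net = _random_net(M=3, p=2, seed=6)
        perm = np.array([2, 0, 1])
        # relabel channels: permute input columns within each lag block
        # and output rows
        W1p = net.W1.copy()
        for lag in range(net.p):
            W1p[:, lag * 3 : (lag + 1) * 3] = net.W1[:, lag * 3 : (lag + 1) * 3][:, perm]
        pnet = NMVARNet(M=3, p=2, W1=W1p, b1=net.b1, W2=net.W2[perm], b2=net.b2[perm])
        lC, lCp = linear_connectivity(net), linear_connectivity(pnet)
        assert np.allclose(lCp, lC[np.ix_(perm, perm)])


class TestNonlinearConnectivity:
    def test_constant_network_has_exactly_zero_nc(self):
        net = _random_net(seed=5)
        net.W2[:] = 0.0  # predictions ignore inputs -> both errors equal
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100, 4))
        Y = rng.standard_normal((100, 2))
        assert np.allclose(nonlinear_connectivity(net, X=X, Y=Y), 0.0)

    def test_perfect_fit_rejected(self):
        net = _random_net(seed=8)
        X = np.random.default_rng(0).standard_normal((20, 4))
        with pytest.raises(ZeroDivisionError):
            nonlinear_connectivity(net, X=X, Y=net.predict(X))

    def test_linear_data_yields_near_zero_nc(self, var2_fit, var2_data):
        data, _ = var2_data
        NC = nonlinear_connectivity(var2_fit, data=data)
        assert np.abs(NC).mean() < 0.05

    def test_nonlinear_edge_detected_on_single_system(self, fast_train):
        A = np.diag([0.5, 0.5])[None]
        base = LinearVARSpec(M=2, p_true=1, A=A, n_samples=2000, seed=3)
        spec = NonlinearVARSpec(
            base, [NLTerm(target=1, source=0, lag=1, form="square", gain=0.4)]
        )
        data = gen_nonlinear_var(spec)[0].data[:, :, 0]
        fit = fit_ncreann(data, 1, fast_train)
        NC = nonlinear_connectivity(fit, data=data)
        assert NC[0, 1] > NC[1, 0]

    def test_retrain_reading_agrees_on_linear_null(self, var2_data, fast_train):
        data, _ = var2_data
        cfg = dataclasses.replace(fast_train, nc_mode="retrain", max_epochs=30)
        NC = nonlinear_connectivity_retrain(data[:, :1500], 1, cfg)
        assert np.abs(NC).mean() < 0.2

    def test_permutation_equivariance_of_nc(self):
        net = _random_net(M=3, p=1, seed=12)
        rng = np.random.default_rng(3)
        X = rng.standard_normal((300, 3))
        Y = rng.standard_normal((300, 3))
        perm = np.array([1, 2, 0])
        pnet = NMVARNet(
            M=3, p=1, W1=net.W1[:, perm], b1=net.b1, W2=net.W2[perm], b2=net.b2[perm]
        )
        NC = nonlinear_connectivity(net, X=X, Y=Y)
        NCp = nonlinear_connectivity(pnet, X=X[:, perm], Y=Y[:, perm])
        assert np.allclose(NCp, NC[np.ix_(perm, perm)])


class TestSurrogates:
    def test_zero_surrogates_rejected(self, fast_train):
        data = np.random.default_rng(0).standard_normal((2, 300))
        with pytest.raises(ValueError, match="n_surr"):
            surrogate_test(data, 1, fast_train, n_surr=0)

    def test_strong_edge_is_detected(self):
        cfg = TrainConfig(folds=2, max_epochs=40, patience=8)
        hits = 0
        for seed in range(10):
            A = np.zeros((1, 2, 2))
            A[0] = [[0.5, 0.0], [0.4, 0.5]]
            spec = LinearVARSpec(M=2, p_true=1, A=A, n_samples=800, seed=seed)
            data = gen_linear_var(spec)[0].data[:, :, 0]
            res = surrogate_test(
                data, 1, dataclasses.replace(cfg, seed=seed), n_surr=40, seed=seed
            )
            hits += bool(res.sig_lC[0, 1])
        assert hits >= 9

    def test_result_carries_masks_and_metrics(self, fast_train):
        data = np.random.default_rng(4).standard_normal((2, 400))
        res = surrogate_test(data, 1, fast_train, n_surr=5, seed=0)
        assert res.sig_lC.shape == (2, 2) and res.sig_NC.shape == (2, 2)
        assert not res.sig_lC[0, 0] and not res.sig_NC[1, 1]  # diagonal never flagged
        assert np.isfinite(res.r2_test)


class TestLaggedDesign:
    def test_lag_major_ordering(self):
        data = np.arange(12, dtype=float).reshape(2, 6)
        X, Y = lagged_design(data, 2)
        # first row: targets at t=2, inputs [x(t-1) both ch, x(t-2) both ch]
        assert Y[0].tolist() == [2.0, 8.0]
        assert X[0].tolist() == [1.0, 7.0, 0.0, 6.0]

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            lagged_design(np.zeros((2, 3)), 5)
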