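"""Inverse-Laplace solver tests: oracle equivalence, recovery, invariants."""

import numpy as np
import pytest
from scipy import optimize

from ripenmr import ilt, models, synth
from ripenmr.errors import CompressionError, GridError, InvalidSchemeError
from ripenmr.models import (AcquisitionScheme, ComponentMixture, EchoTrain,
                            RelaxationComponent)


def brute_force_objective(K, s, lam):
    """Independent minimizer of ||K p - s||^2 + lam sum(p), p >= 0.

    Bound-constrained quasi-Newton on the exact objective; shares no code
    with the FISTA path.
    """
    n = K.shape[1]

    def f(p):
        r = K @ p - s
        return float(r @ r + lam * p.sum())

    def grad(p):
        return 2.0 * K.T @ (K @ p - s) + lam

    best = None
    for x0 in (np.zeros(n), np.full(n, 0.1), np.full(n, 1.0)):
        res = optimize.minimize(f, x0, jac=grad, method="L-BFGS-B",
                                bounds=[(0, None)] * n,
                                options={"maxiter": 5000, "ftol": 1e-16,
                                         "gtol": 1e-12})
        if best is None or res.fun < best:
            best = res.fun
    return best


class TestGrid:
    def test_log_spacing(self):
        g = ilt.default_t2_grid(16)
        (t2,) = g.axes()
        assert t2[0] == pytest.approx(1e-4)
        assert t2[-1] == pytest.approx(1.0)
        ratios = t2[1:] / t2[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_validation(self):
        with pytest.raises(GridError):
            ilt.LogGrid(("T2",), (0.0,), (1.0,), (16,))
        with pytest.raises(GridError):
            ilt.LogGrid(("T2",), (1e-4,), (1.0,), (4,))
        with pytest.raises(GridError):
            ilt.LogGrid(("T1", "T2"), (1e-3,), (1.0, 1.0), (16, 16))


class TestOracleEquivalence:
    """FISTA objective matches a dense brute-force solver on tiny instances."""

    @pytest.mark.parametrize("lam", [1e-4, 1e-2, 0.3])
    def test_1d_objective(self, lam):
        scheme = AcquisitionScheme("cpmg", tau=1e-3, n_echoes=8)
        grid = ilt.LogGrid(("T2",), (1e-3,), (0.3,), (8,))
        mix = ComponentMixture([RelaxationComponent(1.0, 1.0, 5e-3),
                                RelaxationComponent(0.5, 1.0, 80e-3)])
        train = models.forward_signal(mix, scheme)
        m = ilt.invert_1d(train, grid, ilt.RegParams(lam=lam), tol=1e-11)
        K = ilt.build_kernels(scheme, grid)[0]
        f_fista = (np.linalg.norm(K @ m.weights - train.values) ** 2
                   + lam * m.weights.sum())
        f_oracle = brute_force_objective(K, train.values, lam)
        assert f_fista == pytest.approx(f_oracle, rel=1e-6, abs=1e-12)

    def test_2d_objective_uncompressed(self):
        t1 = tuple(np.logspace(-3, 0.4, 6))
        scheme = AcquisitionScheme("satrec_cpmg", tau=1e-3, n_echoes=10,
                                   t1_list=t1)
        grid = ilt.LogGrid(("T1", "T2"), (5e-3, 1e-3), (2.0, 0.3), (9, 8))
        mix = ComponentMixture([RelaxationComponent(1.0, 0.3, 30e-3)])
        train = models.forward_signal(mix, scheme)
        lam = 1e-3
        m = ilt.invert_2d(train, grid, ilt.RegParams(lam=lam), compress=False,
                          tol=1e-11)
        K1, K2 = ilt.build_kernels(scheme, grid)
        Kfull = np.kron(K1, K2)          # (n1*n2) x (m1*m2)
        f_fista = (np.linalg.norm(K1 @ m.weights @ K2.T - train.values) ** 2
                   + lam * m.weights.sum())
        f_oracle = brute_force_objective(Kfull, train.values.ravel(), lam)
        assert f_fista == pytest.approx(f_oracle, rel=1e-6, abs=1e-12)


class TestRecovery:
    def test_noiseless_on_node_delta_recovery(self):
        scheme = AcquisitionScheme("cpmg", tau=1e-4, n_echoes=256)
        grid = ilt.LogGrid(("T2",), (1e-3,), (1.0,), (32,))
        t2_true = grid.axes()[0][17]
        mix = ComponentMixture([RelaxationComponent(1.0, 1.0, t2_true)])
        train = models.forward_signal(mix, scheme)
        m = ilt.invert_1d(train, grid)
        near = m.weights[16:19].sum()
        assert near >= 0.95 * m.weights.sum()
        assert m.weights.sum() == pytest.approx(1.0, rel=0.05)

    def test_noiseless_2d_delta_recovery(self, satrec_scheme):
        mix = ComponentMixture([RelaxationComponent(1.0, 320e-3, 60e-3)])
        train = models.forward_signal(mix, satrec_scheme)
        grid = ilt.default_t1t2_grid(32, 40)
        m = ilt.invert_2d(train, grid)
        t1ax, t2ax = grid.axes()
        i, j = np.unravel_index(np.argmax(m.weights), m.weights.shape)
        assert t1ax[i] == pytest.approx(320e-3, rel=0.15)
        assert t2ax[j] == pytest.approx(60e-3, rel=0.15)

    def test_compression_matches_uncompressed(self):
        t1 = tuple(np.logspace(-3, 0.4, 16))
        scheme = AcquisitionScheme("satrec_cpmg", tau=1e-4, n_echoes=64,
                                   t1_list=t1)
        grid = ilt.LogGrid(("T1", "T2"), (1e-3, 1e-4), (5.0, 1.0), (12, 12))
        mix = ComponentMixture([RelaxationComponent(0.7, 320e-3, 60e-3),
                                RelaxationComponent(0.3, 160e-3, 2.4e-3)])
        train = models.forward_signal(mix, scheme)
        lam = 1e-3
        on = ilt.invert_2d(train, grid, ilt.RegParams(lam=lam), compress=True)
        off = ilt.invert_2d(train, grid, ilt.RegParams(lam=lam),
                            compress=False)
        scale = max(on.weights.max(), off.weights.max())
        np.testing.assert_allclose(on.weights, off.weights,
                                   atol=0.01 * scale)

    def test_round_trip_residual_bound(self, satrec_scheme, day1_mixture):
        """Forward model of the inverted map reproduces the input train."""
        train = models.forward_signal(day1_mixture, satrec_scheme)
        grid = ilt.default_t1t2_grid(32, 40)
        m = ilt.invert_2d(train, grid)
        mix_back = ilt.map_to_mixture(m, min_weight=1e-12)
        recon = models.forward_signal(mix_back, satrec_scheme).values
        resid = np.linalg.norm(recon - train.values)
        assert resid <= 1.05 * m.residual_norm + 1e-9
        assert m.residual_norm <= 0.02 * np.linalg.norm(train.values)


class TestSolverContracts:
    def test_nonnegative_and_monotone_objective(self, make_noisy_train,
                                                t2_mixture, cpmg_scheme):
        train = make_noisy_train(t2_mixture, cpmg_scheme, 100, seed=3)
        m = ilt.invert_1d(train)
        assert np.all(m.weights >= 0)
        hist = np.array(m.flags["objective_history"])
        assert np.all(np.diff(hist) <= 1e-12)

    def test_all_zero_signal_yields_null_map(self, cpmg_scheme):
        train = EchoTrain(cpmg_scheme, np.zeros(512))
        m = ilt.invert_1d(train, reg=ilt.RegParams(lam=1e-3))
        assert m.flags.get("null_map")
        assert m.total_weight == 0.0

    def test_scheme_kind_checked(self, satrec_scheme, cpmg_scheme,
                                 day1_mixture):
        train2d = models.forward_signal(day1_mixture, satrec_scheme)
        with pytest.raises(InvalidSchemeError):
            ilt.invert_1d(train2d)
        train1d = models.forward_signal(day1_mixture, cpmg_scheme)
        with pytest.raises(InvalidSchemeError):
            ilt.invert_2d(train1d)

    def test_overtruncation_raises(self, satrec_scheme, day1_mixture):
        train = models.forward_signal(day1_mixture, satrec_scheme)
        with pytest.raises(CompressionError):
            ilt.invert_2d(train, ilt.default_t1t2_grid(16, 16),
                          ilt.RegParams(lam=1e-3), sv_tol=0.9999)


class TestRegularizationChoice:
    def test_noiseless_returns_ladder_floor(self, t2_mixture, cpmg_scheme):
        train = models.forward_signal(t2_mixture, cpmg_scheme)
        reg = ilt.choose_regularization(train)
        kernels = ilt.build_kernels(cpmg_scheme, ilt.default_t2_grid())
        lam_max = ilt._lambda_max(np.eye(1), kernels[0],
                                  train.values[None, :])
        assert reg.lam == pytest.approx(1e-6 * lam_max)

    def test_discrepancy_residual_matches_target(self, make_noisy_train,
                                                 t2_mixture, cpmg_scheme):
        train = make_noisy_train(t2_mixture, cpmg_scheme, 100, seed=7)
        reg = ilt.choose_regularization(train)
        assert reg.warning is None
        m = ilt.invert_1d(train, reg=reg)
        assert m.residual_norm == pytest.approx(reg.target_residual, rel=0.12)

    def test_lambda_monotone_in_noise(self, make_noisy_train, t2_mixture,
                                      cpmg_scheme):
        train = make_noisy_train(t2_mixture, cpmg_scheme, 100, seed=7)
        lam1 = ilt.choose_regularization(train).lam
        lam2 = ilt.choose_regularization(
            train, noise_sigma=2 * train.noise_sigma).lam
        assert lam2 >= lam1

    def test_fixed_passthrough(self, cpmg_scheme, t2_mixture):
        train = models.forward_signal(t2_mixture, cpmg_scheme)
        reg = ilt.choose_regularization(train, strategy="fixed", lam=0.25)
        assert reg.lam == 0.25
        with pytest.raises(GridError):
            ilt.choose_regularization(train, strategy="fixed")
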