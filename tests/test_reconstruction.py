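import numpy as np
import pytest
import scipy.sparse as sp

from rivalnet import (ModelParams, StimulusImage, assemble_system, dct2,
                      idct2, l1_solve, omp_solve, relative_error)
from rivalnet.network import NetworkRealization
from rivalnet.reconstruction import LinearSystem, _omp_greedy
from rivalnet.simulator import WindowStats


class TestRelativeError:
    def test_identity(self):
        img = StimulusImage(np.random.default_rng(0).random((4, 4)))
        assert relative_error(img, img) == 0.0

    def test_zero_reconstruction(self):
        img = StimulusImage(np.ones((4, 4)))
        assert relative_error(img, np.zeros((4, 4))) == pytest.approx(1.0)

    def test_double_reconstruction(self):
        img = StimulusImage(np.ones((4, 4)))
        assert relative_error(img, 2 * img.pixels) == pytest.approx(1.0)

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            relative_error(np.zeros(4), np.zeros(4))


class TestGreedyCore:
    def test_exact_recovery_of_sparse_signal(self):
        # 3-sparse coefficient vector, 200 x 1000 Bernoulli matrix
        rng = np.random.default_rng(3)
        A = (rng.random((200, 1000)) < 0.05).astype(float)
        x = np.zeros(1000)
        support = [17, 404, 777]
        x[support] = [2.0, -1.5, 0.7]
        b = A @ x

        sel, coef, r = _omp_greedy(lambda res: A.T @ res,
                                   lambda j: A[:, j], b, 1000, 10, 1e-12)
        assert sorted(sel) == support
        assert np.linalg.norm(r) < 1e-10

    def test_l1_cross_check_agrees(self):
        # basis pursuit and OMP recover the same sparse solution
        rng = np.random.default_rng(4)
        A = rng.standard_normal((30, 80))
        x = np.zeros(80)
        x[[5, 40]] = [1.0, -2.0]
        b = A @ x
        sel, coef, _ = _omp_greedy(lambda res: A.T @ res,
                                   lambda j: A[:, j], b, 80, 5, 1e-12)
        x_omp = np.zeros(80)
        x_omp[sel] = coef
        x_l1 = l1_solve(A, b)
        assert np.allclose(x_omp, x, atol=1e-8)
        assert np.allclose(x_l1, x, atol=1e-6)


def _system_from_image(pixels, m_rows=60, seed=0, **kw):
    rng = np.random.default_rng(seed)
    side = pixels.shape[0]
    F = sp.csr_matrix((rng.random((m_rows, side * side)) < 0.1).astype(float))
    b = np.asarray(F @ pixels.ravel()).ravel()
    return LinearSystem(measurement_matrix=F, observation=b, side=side, **kw)


class TestOMPSolve:
    def test_constant_image_single_atom(self):
        img = np.full((12, 12), 0.7)
        res = omp_solve(_system_from_image(img), sparsity_budget=5)
        assert res.atoms_used == 1
        assert relative_error(img, res.percept) < 1e-6

    def test_budget_zero_returns_zero_image(self):
        img = np.full((8, 8), 1.0)
        res = omp_solve(_system_from_image(img), sparsity_budget=0)
        assert res.atoms_used == 0
        assert relative_error(img, res.percept) == pytest.approx(1.0)

    def test_zero_observation_flagged_not_raised(self):
        sys_ = _system_from_image(np.zeros((8, 8)))
        res = omp_solve(sys_, sparsity_budget=4)
        assert res.atoms_used == 0
        assert np.all(res.percept == 0)

    def test_budget_must_be_under_rows(self):
        with pytest.raises(ValueError):
            omp_solve(_system_from_image(np.ones((8, 8))),
                      sparsity_budget=60)

    def test_sparse_dct_image_recovered(self):
        side = 16
        coef = np.zeros((side, side))
        coef[0, 2] = 3.0
        coef[1, 0] = -1.0
        coef[3, 3] = 0.5
        img = idct2(coef)
        res = omp_solve(_system_from_image(img, m_rows=100, seed=1),
                        sparsity_budget=10)
        assert relative_error(img, res.percept) < 1e-6
        assert res.atoms_used <= 10

    def test_clipped_image_nonnegative(self):
        side = 8
        coef = np.zeros((side, side))
        coef[0, 1] = 1.0
        img = idct2(coef)  # oscillates around zero
        res = omp_solve(_system_from_image(img), sparsity_budget=4)
        assert res.clipped_image().pixels.min() >= 0.0


class TestAssembleSystem:
    def _setup(self):
        p = ModelParams(N_E=3, N_I=3, K=2, n_pixels=9, dt=0.1)
        rng = np.random.default_rng(7)
        M = p.M
        R1 = sp.csc_matrix(rng.standard_normal((M, M)) * 0.1)
        R2 = sp.csc_matrix(rng.standard_normal((M, M)) * 0.1)
        C1 = sp.csc_matrix(np.abs(rng.standard_normal((M, M))) * 0.05)
        C2 = sp.csc_matrix(np.abs(rng.standard_normal((M, M))) * 0.05)
        F1 = sp.csc_matrix(rng.random((M, 9)))
        F2 = sp.csc_matrix(rng.random((M, 9)))
        net = NetworkRealization(R1=R1, R2=R2, C1=C1, C2=C2, F1=F1, F2=F2)
        return p, net

    def _stats(self, p, rate, vmean, thmean):
        z = np.zeros(2 * p.M)
        return WindowStats(rate=rate, vmean=vmean, thmean=thmean,
                           reset_rate=z.copy(), clamp_rate=z.copy())

    def test_algebraic_inversion_of_forward_map(self):
        # set v_bar to the forward-map prediction exactly: the assembled
        # observation then equals F @ p_true to machine precision
        from rivalnet import predict_mean_voltages

        p, net = self._setup()
        M = p.M
        rng = np.random.default_rng(8)
        p_true = StimulusImage(rng.random((3, 3)))
        m1 = rng.random(M) * 0.2
        m2 = rng.random(M) * 0.2
        th = np.ones(M) * 1.1
        v1 = predict_mean_voltages(net, p_true, m1, m2, th, p, pool=1)
        rate = np.concatenate([m1, m2])
        vmean = np.concatenate([v1, np.zeros(M)])
        thmean = np.concatenate([th, np.ones(M)])
        sys_ = assemble_system(net, self._stats(p, rate, vmean, thmean), 1, p,
                               reset_accounting="threshold")
        expect = np.asarray(net.F1 @ p_true.vector).ravel()
        assert np.allclose(sys_.observation, expect, atol=1e-12)

    def test_zero_activity_gives_zero_observation(self):
        p, net = self._setup()
        z = np.zeros(2 * p.M)
        sys_ = assemble_system(
            net, self._stats(p, z, z + p.V_Re, np.ones(2 * p.M)), 1, p,
            reset_accounting="threshold")
        assert np.allclose(sys_.observation, 0.0)

    def test_pool_swap_uses_other_feedforward(self):
        p, net = self._setup()
        z = np.zeros(2 * p.M)
        s1 = assemble_system(net, self._stats(p, z, z, np.ones(2 * p.M)), 1, p)
        s2 = assemble_system(net, self._stats(p, z, z, np.ones(2 * p.M)), 2, p)
        assert s1.measurement_matrix.shape == s2.measurement_matrix.shape
        assert (s1.measurement_matrix != net.F1.tocsr()).nnz == 0
        assert (s2.measurement_matrix != net.F2.tocsr()).nnz == 0

    def test_measured_accounting_requires_flux_fields(self):
        p, net = self._setup()
        z = np.zeros(2 * p.M)
        with pytest.raises(ValueError):
            assemble_system(net, (z, z, np.ones(2 * p.M)), 1, p,
                            reset_accounting="measured")
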