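"""Cayley map, smoothness functionals, analytic gradients and descrambling."""

import numpy as np
import pytest
from scipy.stats import ortho_group, special_ortho_group

from deerdescramble import descrambler as dsc
from deerdescramble import network as nw


def random_generator(d, seed, scale=0.5):
    rng = np.random.default_rng(seed)
    return dsc.AntisymmetricGenerator(
        rng.normal(scale=scale, size=d * (d - 1) // 2), d)


def smooth_columns_matrix(d, n_cols, seed, n_modes=5):
    """Matrix whose columns live in a low-frequency Fourier subspace."""
    rng = np.random.default_rng(seed)
    j = np.arange(d)
    modes = [np.ones(d)]
    for m in range(1, n_modes):
        modes += [np.cos(2 * np.pi * m * j / d), np.sin(2 * np.pi * m * j / d)]
    B = np.column_stack(modes)
    return B @ rng.normal(size=(B.shape[1], n_cols))


class TestCayley:
    def test_zero_gives_identity(self):
        assert np.array_equal(dsc.cayley(dsc.AntisymmetricGenerator.zero(6)), np.eye(6))

    def test_two_dimensional_rotation_oracle(self):
        # direct 2x2 arithmetic: (1-Q)(1+Q)^-1 with Q = [[0,1],[-1,0]]
        p = dsc.cayley(dsc.AntisymmetricGenerator([1.0], 2))
        assert np.allclose(p, [[0.0, -1.0], [1.0, 0.0]], atol=1e-15)

    def test_special_orthogonal(self):
        for seed in range(5):
            p = dsc.cayley(random_generator(16, seed))
            assert np.linalg.norm(p @ p.T - np.eye(16)) < 1e-12
            sign, logdet = np.linalg.slogdet(p)  # decomposition-based oracle
            assert sign == 1.0 and abs(logdet) < 1e-10

    def test_group_identities(self):
        q = random_generator(8, 3)
        p = dsc.cayley(q)
        p_neg = dsc.cayley(dsc.AntisymmetricGenerator(-q.params, 8))
        assert np.allclose(p_neg, p.T, atol=1e-12)
        assert np.allclose(p_neg @ p, np.eye(8), atol=1e-12)

    def test_operator_orders_commute(self):
        Q = random_generator(12, 1).matrix
        eye = np.eye(12)
        left = (eye - Q) @ np.linalg.inv(eye + Q)
        right = np.linalg.inv(eye + Q) @ (eye - Q)
        assert np.allclose(left, right, atol=1e-12)
        assert np.allclose(dsc.cayley(Q), left, atol=1e-12)

    def test_rejects_non_antisymmetric(self):
        with pytest.raises(ValueError):
            dsc.cayley(np.eye(3))


class TestSpectralSecondDerivative:
    def test_annihilates_constants(self):
        D = dsc.spectral_second_derivative(16)
        assert np.max(np.abs(D.matrix @ np.ones(16))) < 1e-10

    def test_harmonic_eigenvector(self):
        d = 32
        D = dsc.spectral_second_derivative(d)
        v = np.cos(2 * np.pi * np.arange(d) / d)
        assert np.allclose(D.matrix @ v, -(2 * np.pi) ** 2 * v, atol=1e-8)

    def test_symmetric_and_matches_dft_oracle(self):
        d = 16
        D = dsc.spectral_second_derivative(d).matrix
        assert np.max(np.abs(D - D.T)) < 1e-10
        # oracle: diagonalize by the DFT explicitly
        F = np.fft.fft(np.eye(d)) / np.sqrt(d)
        k = np.fft.fftfreq(d, d=1.0 / d)
        oracle = np.real(F.conj().T @ np.diag(-(2 * np.pi * k) ** 2) @ F)
        assert np.allclose(D, oracle, atol=1e-8)

    def test_odd_dimension_unsupported(self):
        with pytest.raises(ValueError):
            dsc.spectral_second_derivative(15)


class TestTikhonovNorm:
    def test_constant_columns_zero(self):
        D = dsc.spectral_second_derivative(8)
        V = np.outer(np.ones(8), [1.0, -2.0, 3.0])
        assert dsc.tikhonov_norm(V, D) == pytest.approx(0.0, abs=1e-12)

    def test_column_additivity(self, rng):
        D = dsc.spectral_second_derivative(10)
        v1, v2 = rng.normal(size=10), rng.normal(size=10)
        total = dsc.tikhonov_norm(np.column_stack([v1, v2]), D)
        assert total == pytest.approx(dsc.tikhonov_norm(v1, D) + dsc.tikhonov_norm(v2, D),
                                      rel=1e-12)

    @pytest.mark.parametrize("m", [1, 2, 5])
    def test_harmonic_closed_form(self, m):
        d = 64
        D = dsc.spectral_second_derivative(d)
        v = np.sin(2 * np.pi * m * np.arange(d) / d)
        expected = (2 * np.pi * m) ** 4 * float(v @ v)
        assert dsc.tikhonov_norm(v, D) == pytest.approx(expected, rel=1e-6)


class TestIntermediateSignals:
    def test_single_layer_taps(self, rng):
        net = nw.init_network(5, [nw.LayerSpec(4, "sigmoid")], seed=0)
        X = rng.normal(size=(5, 6))
        pre = dsc.intermediate_signals(net, X, 0, "before_activation")
        assert np.allclose(pre, net.weights[0] @ X + net.biases[0][:, None], atol=1e-14)
        post = dsc.intermediate_signals(net, X, 0, "after_activation")
        assert np.allclose(post, np.tanh(pre), atol=1e-14)

    def test_matches_truncated_forward_oracle(self, rng):
        specs = [nw.LayerSpec(6, "sigmoid"), nw.LayerSpec(5, "logsig"),
                 nw.LayerSpec(4, "identity")]
        net = nw.init_network(7, specs, seed=1)
        X = rng.normal(size=(7, 8))
        post1 = dsc.intermediate_signals(net, X, 1, "after_activation")
        # oracle: run the truncated sub-network through the public forward
        sub = nw.NetworkWeights(net.weights[:2], net.biases[:2], specs[:2])
        assert np.allclose(post1, nw.forward(sub, X), atol=1e-14)


class TestObjectiveAndGradient:
    def _problem(self, seed, objective="tikhonov", tap="before_activation"):
        d = 8
        rng = np.random.default_rng(seed)
        net = nw.init_network(d, [nw.LayerSpec(d, "sigmoid"),
                                  nw.LayerSpec(d, "logsig")], seed=seed)
        X = rng.normal(size=(d, 25))
        return dsc.DescramblerProblem(net=net, layer_index=0, tap=tap,
                                      objective=objective, X=X), d

    def test_zero_signals_zero_objective(self):
        problem, d = self._problem(0)
        problem.X = np.zeros((d, 10))
        # bias still contributes constant columns; remove it for the pure-zero case
        problem.net.biases[0][:] = 0.0
        value, grad = dsc.objective_and_gradient(random_generator(d, 1), problem)
        assert value == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(grad, 0.0, atol=1e-18)

    def test_identity_point_equals_raw_tikhonov(self):
        problem, d = self._problem(2)
        value, _ = dsc.objective_and_gradient(dsc.AntisymmetricGenerator.zero(d), problem)
        D = dsc.spectral_second_derivative(d)
        M = dsc.intermediate_signals(problem.net, problem.X, 0, "before_activation")
        assert value == pytest.approx(dsc.tikhonov_norm(M, D), rel=1e-12)

    @pytest.mark.parametrize("objective,tap", [
        ("tikhonov", "before_activation"),
        ("tikhonov", "after_activation"),
        ("tikhonov_plus_link", "after_activation"),
        ("max_diag_sum", "before_activation"),
        ("max_diag_normsq", "before_activation"),
    ])
    def test_gradient_matches_finite_differences(self, objective, tap):
        problem, d = self._problem(5, objective=objective, tap=tap)
        gen = random_generator(d, 6, scale=0.3)
        ops = dsc._problem_operators(problem)

        def value_at(params):
            Q = dsc.AntisymmetricGenerator(params, d).matrix
            return dsc._value_and_grad_p(dsc.cayley(Q), ops)[0]

        h = 1e-6
        n = gen.params.size
        fd = np.array([
            (value_at(gen.params + h * np.eye(n)[i])
             - value_at(gen.params - h * np.eye(n)[i])) / (2 * h)
            for i in range(n)])
        Q = gen.matrix
        P = dsc.cayley(Q)
        analytic = dsc._grad_q_params(dsc._value_and_grad_p(P, ops)[1], P, Q)
        assert np.linalg.norm(analytic - fd) / np.linalg.norm(fd) < 1e-6

    def test_batched_accumulation_matches_whole_array(self):
        problem, d = self._problem(7)
        whole = dsc._signal_gram(problem)
        problem.batch_size = 7
        batched = dsc._signal_gram(problem)
        assert np.allclose(whole, batched, atol=1e-10)


class TestDescramble:
    def test_zero_input_stays_at_identity(self):
        d = 8
        net = nw.init_network(d, [nw.LayerSpec(d, "identity")], seed=0)
        net.biases[0][:] = 0.0
        problem = dsc.DescramblerProblem(net=net, layer_index=0,
                                         tap="before_activation",
                                         objective="tikhonov", X=np.zeros((d, 5)))
        res = dsc.descramble(problem)
        assert np.allclose(res.p_star, np.eye(d), atol=1e-12)
        assert res.converged

    def test_planted_scrambling_recovered(self):
        d, n_cols = 16, 64
        for seed in range(3):
            W_smooth = smooth_columns_matrix(d, 20, seed)
            R = special_ortho_group.rvs(d, random_state=seed)
            W = R.T @ W_smooth
            X = np.random.default_rng(100 + seed).normal(size=(20, n_cols))
            net = nw.NetworkWeights([W], [np.zeros(d)], [nw.LayerSpec(d, "identity")])
            problem = dsc.DescramblerProblem(net=net, layer_index=0,
                                             tap="before_activation",
                                             objective="tikhonov", X=X)
            res = dsc.descramble(problem)
            D = dsc.spectral_second_derivative(d)
            planted = dsc.tikhonov_norm(W_smooth @ X, D)
            assert res.objective_history[-1] <= 1.05 * planted
            # objective history is monotone non-increasing
            assert np.all(np.diff(res.objective_history) <= 1e-9)
            # orthogonal invariance of the singular values
            sv0 = np.linalg.svd(W, compute_uv=False)
            sv1 = np.linalg.svd(res.p_star @ W, compute_uv=False)
            assert np.max(np.abs(sv0 - sv1)) < 1e-10

    def test_result_in_special_orthogonal_group(self):
        d = 12
        net = nw.init_network(d, [nw.LayerSpec(d, "sigmoid")], seed=2)
        X = np.random.default_rng(2).normal(size=(d, 40))
        problem = dsc.DescramblerProblem(net=net, layer_index=0,
                                         tap="before_activation",
                                         objective="tikhonov", X=X)
        res = dsc.descramble(problem, dsc.DescrambleConfig(maxiter=100))
        assert np.linalg.norm(res.p_star @ res.p_star.T - np.eye(d)) < 1e-8
        assert np.linalg.det(res.p_star) == pytest.approx(1.0, abs=1e-6)


class TestDiagonalObjectives:
    def test_identity_trace(self):
        q = dsc.AntisymmetricGenerator.zero(5)
        assert dsc.diagonal_objectives(q, np.eye(5)) == pytest.approx(5.0)
        assert dsc.diagonal_objectives(q, np.eye(5), "max_diag_normsq") == pytest.approx(5.0)

    def test_planted_rotation_angle_scan_oracle(self):
        # maximizing Tr(P W) over SO(2) with W a rotation should invert it
        theta = 0.9
        W = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        angles = np.linspace(-np.pi, np.pi, 100_001)
        traces = 2 * np.cos(angles + theta)  # Tr(R(a) W) brute force
        best = angles[np.argmax(traces)]
        net = nw.NetworkWeights([W], [np.zeros(2)], [nw.LayerSpec(2, "identity")])
        problem = dsc.DescramblerProblem(net=net, layer_index=0,
                                         tap="before_activation",
                                         objective="max_diag_sum",
                                         X=np.zeros((2, 1)))
        res = dsc.descramble(problem)
        found = np.arctan2(res.p_star[1, 0], res.p_star[0, 0])
        assert found == pytest.approx(best, abs=1e-4)
        assert dsc.diagonal_objectives(res.q_star, W) == pytest.approx(2.0, abs=1e-8)

    def test_von_neumann_trace_inequality(self, rng):
        W = rng.normal(size=(6, 6))
        bound = np.linalg.svd(W, compute_uv=False).sum()
        for seed in range(10):
            val = dsc.diagonal_objectives(random_generator(6, seed, 1.0), W)
            assert val <= bound + 1e-10

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            dsc.diagonal_objectives(dsc.AntisymmetricGenerator.zero(3),
                                    np.ones((3, 4)))


class TestApplyDescrambler:
    def _net(self, seed=0):
        return nw.init_network(6, [nw.LayerSpec(6, "sigmoid"),
                                   nw.LayerSpec(5, "logsig")], seed=seed)

    def test_identity_is_noop(self, rng):
        net = self._net()
        out = dsc.apply_descrambler(net, 0, "before_activation", np.eye(6))
        X = rng.normal(size=(6, 4))
        assert np.array_equal(nw.forward(out, X), nw.forward(net, X))

    @pytest.mark.parametrize("tap", ["before_activation", "after_activation"])
    def test_outputs_preserved(self, tap, rng):
        net = self._net(1)
        P = special_ortho_group.rvs(6, random_state=4)
        out = dsc.apply_descrambler(net, 0, tap, P)
        X = rng.normal(size=(6, 10))
        y0, y1 = nw.forward(net, X), nw.forward(out, X)
        assert np.max(np.abs(y0 - y1)) / np.max(np.abs(y0)) < 1e-8

    def test_last_layer_after_tap_records_output_undo(self, rng):
        net = self._net(2)
        P = special_ortho_group.rvs(5, random_state=5)
        out = dsc.apply_descrambler(net, 1, "after_activation", P)
        assert out.output_undo is not None
        X = rng.normal(size=(6, 10))
        assert np.allclose(nw.forward(out, X), nw.forward(net, X), atol=1e-10)

    def test_group_inverse_restores_weights(self):
        net = self._net(3)
        P = special_ortho_group.rvs(6, random_state=6)
        twice = dsc.apply_descrambler(
            dsc.apply_descrambler(net, 0, "before_activation", P),
            0, "before_activation", P.T)
        assert np.allclose(twice.weights[0], net.weights[0], atol=1e-10)
        assert np.allclose(twice.biases[0], net.biases[0], atol=1e-10)
        assert twice.pre_undo[0] is None

    def test_descrambled_tap_signals_are_rotated(self, rng):
        net = self._net(4)
        P = special_ortho_group.rvs(6, random_state=7)
        out = dsc.apply_descrambler(net, 0, "before_activation", P)
        X = rng.normal(size=(6, 5))
        raw = dsc.intermediate_signals(net, X, 0, "before_activation")
        rotated = dsc.intermediate_signals(out, X, 0, "before_activation")
        assert np.allclose(rotated, P @ raw, atol=1e-10)

    def test_non_orthogonal_rejected(self):
        with pytest.raises(ValueError):
            dsc.apply_descrambler(self._net(), 0, "before_activation",
                                  np.eye(6) * 1.5)
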