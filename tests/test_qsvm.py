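"""Kernels (polynomial + simulated quantum feature map) and SVM machinery."""

import numpy as np
import pytest

from cadskin.exceptions import ConfigError, DataError, ShapeError
from cadskin.qsvm import (
    KernelSpec,
    fit_qsvm,
    gram_matrix,
    load_qsvm,
    poly_kernel,
    predict,
    decision_scores,
    quantum_kernel,
    reduce_features,
    save_qsvm,
    soe_statevector,
)

RNG = np.random.default_rng(11)

# ---- dense-unitary statevector oracle --------------------------------------
H1 = np.array([[1.0, 1.0], [1.0, -1.0]]) / np.sqrt(2.0)
ZP = np.diag([1.0, -1.0])
I2 = np.eye(2)


def kron_all(mats):
    out = np.array([[1.0]])
    for m in mats:
        out = np.kron(out, m)
    return out


def oracle_statevector(x, spec):
    n = spec.n_qubits
    xs = spec.scale * np.asarray(x, dtype=float)
    H = kron_all([H1] * n)
    theta = np.zeros((2**n, 2**n))
    for i in range(n):
        theta += xs[i] * kron_all([ZP if q == i else I2 for q in range(n)])
    for i, j in spec.pairs():
        theta += (np.pi - xs[i]) * (np.pi - xs[j]) * kron_all(
            [ZP if q in (i, j) else I2 for q in range(n)]
        )
    U = np.diag(np.exp(1j * np.diag(theta)))
    s = np.zeros(2**n, dtype=complex)
    s[0] = 1.0
    for _ in range(spec.repetitions):
        s = U @ (H @ s)
    return s


class TestPolyKernel:
    def test_unit_vector_self(self):
        x = np.array([1.0, 0.0, 0.0])
        assert poly_kernel(x, x, KernelSpec()) == 1.0

    def test_orthogonal_zero_offset(self):
        assert poly_kernel(np.array([1.0, 0.0]), np.array([0.0, 1.0]), KernelSpec()) == 0.0

    def test_matches_direct_formula(self):
        spec = KernelSpec(degree=3, scale=0.7, offset=0.2)
        x, z = RNG.normal(size=5), RNG.normal(size=5)
        expected = (0.7 * sum(a * b for a, b in zip(x, z)) + 0.2) ** 3
        assert poly_kernel(x, z, spec) == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ShapeError):
            poly_kernel(np.zeros(3), np.zeros(4), KernelSpec())


class TestStatevector:
    def test_zero_vector_uniform_probabilities(self):
        spec = KernelSpec(family="quantum_second_order", n_qubits=3, repetitions=1)
        s = soe_statevector(np.zeros(3), spec)
        np.testing.assert_allclose(np.abs(s) ** 2, 1 / 8, atol=1e-12)
        np.testing.assert_allclose(np.abs(s), 2 ** (-1.5), atol=1e-12)

    def test_unit_norm_random_inputs(self):
        spec = KernelSpec(family="quantum_second_order", n_qubits=4)
        for _ in range(5):
            s = soe_statevector(RNG.uniform(0, np.pi, 4), spec)
            assert abs(np.linalg.norm(s) - 1.0) < 1e-10

    def test_two_qubit_dense_oracle(self):
        spec = KernelSpec(family="quantum_second_order", n_qubits=2)
        x = np.array([0.3, 1.1])
        np.testing.assert_allclose(
            soe_statevector(x, spec), oracle_statevector(x, spec), atol=1e-10
        )

    def test_qubit_bound(self):
        spec = KernelSpec(family="quantum_second_order", n_qubits=13)
        with pytest.raises(ConfigError):
            soe_statevector(np.zeros(13), spec)


class TestQuantumKernel:
    def test_self_kernel_is_one(self):
        spec = KernelSpec(family="quantum_second_order", n_qubits=3)
        for _ in range(5):
            x = RNG.uniform(0, np.pi, 3)
            assert quantum_kernel(x, x, spec) == pytest.approx(1.0, abs=1e-10)

    def test_symmetry(self):
        spec = KernelSpec(family="quantum_second_order", n_qubits=3)
        x, z = RNG.uniform(0, np.pi, 3), RNG.uniform(0, np.pi, 3)
        assert quantum_kernel(x, z, spec) == pytest.approx(
            quantum_kernel(z, x, spec), abs=1e-12
        )

    def test_against_dense_oracle_n3(self):
        spec = KernelSpec(family="quantum_second_order", n_qubits=3)
        for _ in range(10):
            x, z = RNG.uniform(0, np.pi, 3), RNG.uniform(0, np.pi, 3)
            expected = abs(np.vdot(oracle_statevector(x, spec), oracle_statevector(z, spec))) ** 2
            assert quantum_kernel(x, z, spec) == pytest.approx(expected, abs=1e-10)


class TestGram:
    def test_single_sample_quantum(self):
        spec = KernelSpec(family="quantum_second_order", n_qubits=2)
        G = gram_matrix(np.array([[0.5, 1.0]]), spec)
        np.testing.assert_allclose(G, [[1.0]], atol=1e-10)

    @pytest.mark.parametrize("family,nq", [("polynomial", 3), ("quantum_second_order", 3)])
    def test_symmetric_psd(self, family, nq):
        spec = KernelSpec(family=family, n_qubits=nq)
        X = RNG.uniform(0, np.pi, (10, nq))
        G = gram_matrix(X, spec)
        np.testing.assert_allclose(G, G.T, atol=1e-10)
        assert np.linalg.eigvalsh(G).min() >= -1e-8

    def test_matches_entrywise_kernel_calls(self):
        spec = KernelSpec(family="quantum_second_order", n_qubits=2)
        X = RNG.uniform(0, np.pi, (4, 2))
        G = gram_matrix(X, spec)
        for i in range(4):
            for j in range(4):
                assert G[i, j] == pytest.approx(quantum_kernel(X[i], X[j], spec), abs=1e-10)

    def test_nonfinite_rejected(self):
        X = np.array([[0.1, np.nan]])
        with pytest.raises(DataError):
            gram_matrix(X, KernelSpec())


class TestReduceFeatures:
    def test_range_and_variance_ordering(self):
        Z = RNG.normal(size=(50, 10)) * np.array([5, 3, 1, 1, 1, 1, 1, 1, 1, 1])
        X, proj = reduce_features(Z, 3)
        assert X.min() >= -1e-9 and X.max() <= np.pi + 1e-9
        raw = proj.project(Z)
        v = raw.var(axis=0)
        assert v[0] >= v[1] >= v[2]

    def test_projection_reused_for_new_data(self):
        Z = RNG.normal(size=(30, 6))
        X, proj = reduce_features(Z, 2)
        np.testing.assert_allclose(proj.transform(Z), X, atol=1e-12)

    def test_distance_ordering_preserved_when_full_rank(self):
        """With latent dim == target dim the map is a rotation plus per-axis
        affine rescale; ordering of coordinates along each axis is preserved."""
        Z = RNG.normal(size=(20, 2))
        X, proj = reduce_features(Z, 2)
        raw = proj.project(Z)
        for d in range(2):
            assert (np.argsort(raw[:, d]) == np.argsort(X[:, d])).all()

    def test_too_few_samples(self):
        with pytest.raises(DataError):
            reduce_features(np.zeros((1, 5)), 2)


def xor_data():
    X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
    y = np.array([0, 1, 1, 0])
    return X, y


def xor_grid_oracle(C=10.0, step=0.25):
    """Exhaustive small-grid solve of the binary dual for the XOR problem."""
    X, y = xor_data()
    yb = np.where(y == 1, 1.0, -1.0)
    K = (X @ X.T) ** 3
    grid = np.arange(0, C + step / 2, step)
    best, best_alpha = -np.inf, None
    for a1 in grid:
        for a2 in grid:
            for a3 in grid:
                a0 = a1 + a2 - a3  # from sum alpha_i y_i = 0
                if not 0 <= a0 <= C:
                    continue
                a = np.array([a0, a1, a2, a3])
                w = a.sum() - 0.5 * (a * yb) @ K @ (a * yb)
                if w > best:
                    best, best_alpha = w, a
    a = best_alpha
    free = (a > 1e-9) & (a < C - 1e-9)
    sv = np.argmax(free) if free.any() else np.argmax(a > 1e-9)
    b = yb[sv] - ((a * yb) @ K[:, sv])
    scores = (a * yb) @ K + b
    return np.where(scores > 0, 1, 0)


class TestFitPredict:
    def test_separable_pair_perfect(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([0, 1])
        model = fit_qsvm(X, y, KernelSpec(degree=1), C=1.0)
        yp, _ = predict(model, X)
        np.testing.assert_array_equal(yp, y)

    def test_xor_degree_three_matches_grid_oracle(self):
        X, y = xor_data()
        model = fit_qsvm(X, y, KernelSpec(), C=10.0)
        yp, _ = predict(model, X)
        assert (yp == y).all()
        np.testing.assert_array_equal(yp, xor_grid_oracle(C=10.0))

    def test_kkt_invariants(self):
        X, y = xor_data()
        C = 10.0
        model = fit_qsvm(X, y, KernelSpec(), C=C)
        for m in model.machines:
            alpha = np.abs(m.dual_coef)
            assert (alpha <= C + 1e-6).all() and (alpha >= -1e-9).all()
            assert abs(m.dual_coef.sum()) < 1e-6

    def test_bound_support_vector_margin(self):
        """A support vector at alpha = C lies on or inside the margin."""
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (15, 2)), rng.normal(1.0, 1, (15, 2))])
        y = np.array([0] * 15 + [1] * 15)
        C = 1.0
        model = fit_qsvm(X, y, KernelSpec(degree=1), C=C)
        m = model.machines[1]
        scores = decision_scores(model, m.support_vectors)[:, 1]
        bound = np.abs(np.abs(m.dual_coef) - C) < 1e-8
        margins = m.support_labels * scores
        assert (margins[bound] <= 1.0 + 1e-6).all()

    def test_predictions_match_stored_dual_expansion(self):
        """predict() agrees with a brute-force sum over stored alpha, y, d."""
        rng = np.random.default_rng(5)
        X = rng.uniform(0, np.pi, (20, 3))
        y = (X.sum(axis=1) > 1.5 * np.pi).astype(int)
        spec = KernelSpec(family="quantum_second_order", n_qubits=3)
        model = fit_qsvm(X, y, spec, C=1.0)
        Xt = rng.uniform(0, np.pi, (5, 3))
        _, scores = predict(model, Xt)
        for k, m in enumerate(model.machines):
            for t in range(5):
                manual = (
                    sum(
                        coef * quantum_kernel(sv, Xt[t], spec)
                        for coef, sv in zip(m.dual_coef, m.support_vectors)
                    )
                    + m.bias
                )
                assert scores[t, k] == pytest.approx(manual, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            fit_qsvm(np.zeros((4, 2)), np.zeros(4, dtype=int), KernelSpec(), C=1.0)

    def test_invalid_c(self):
        X, y = xor_data()
        with pytest.raises(ConfigError):
            fit_qsvm(X, y, KernelSpec(), C=0.0)

    @pytest.mark.parametrize(
        "family,scale", [("polynomial", 1.0), ("quantum_second_order", 0.25)]
    )
    def test_separated_blobs_both_families(self, family, scale):
        """Two well-separated Gaussian blobs: training accuracy 1.0 and
        held-out accuracy >= 0.95 for both kernel families."""
        rng = np.random.default_rng(0)
        A = rng.normal([0, 0], 1.0, (20, 2))
        B = rng.normal([6, 6], 1.0, (20, 2))
        X = np.vstack([A, B])
        y = np.array([0] * 20 + [1] * 20)
        idx = rng.permutation(40)
        Xtr, ytr, Xte, yte = X[idx[:20]], y[idx[:20]], X[idx[20:]], y[idx[20:]]
        Xp, proj = reduce_features(Xtr, 2)
        spec = KernelSpec(family=family, n_qubits=2, scale=scale)
        model = fit_qsvm(Xp, ytr, spec, C=1.0)
        assert (predict(model, Xp)[0] == ytr).mean() == 1.0
        assert (predict(model, proj.transform(Xte))[0] == yte).mean() >= 0.95

    def test_fit_deterministic(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, np.pi, (30, 2))
        y = (X[:, 0] > X[:, 1]).astype(int)
        m1 = fit_qsvm(X, y, KernelSpec(), C=1.0)
        m2 = fit_qsvm(X, y, KernelSpec(), C=1.0)
        Xt = rng.uniform(0, np.pi, (10, 2))
        np.testing.assert_array_equal(predict(m1, Xt)[0], predict(m2, Xt)[0])


class TestPersistence:
    def test_archive_roundtrip(self, tmp_path):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, np.pi, (20, 2))
        y = (X[:, 0] > 1.5).astype(int)
        Xp, proj = reduce_features(X, 2)
        model = fit_qsvm(Xp, y, KernelSpec(), C=1.0)
        save_qsvm(model, tmp_path / "m.npz", projection=proj)
        loaded, proj2 = load_qsvm(tmp_path / "m.npz")
        Xt = rng.uniform(0, np.pi, (6, 2))
        np.testing.assert_allclose(proj2.transform(Xt), proj.transform(Xt), atol=1e-12)
        np.testing.assert_array_equal(
            predict(loaded, proj2.transform(Xt))[0],
            predict(model, proj.transform(Xt))[0],
        )
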