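"""Kernel SVM over autoencoder features, with a classically simulated
second-order-expansion quantum feature map.

Two kernel families are supported:

* ``polynomial``: K(x, z) = (scale * <x, z> + offset)^degree, the default
  (degree 3, scale 1.0, offset 0.0).
* ``quantum_second_order``: the fidelity kernel K(x, z) = |<phi(x), phi(z)>|^2
  of the statevector feature map phi(x) = [diag-phase . H^(x)n]^reps |0...0>,
  with first-order Pauli-Z angles theta_i = x_i and second-order ZZ angles
  theta_ij = (pi - x_i)(pi - x_j) on each entangled qubit pair (full pairwise
  entanglement and two repetitions by default). Features are expected in
  [0, pi]; ``reduce_features`` produces exactly that scaling.

Multi-class classification is one-vs-rest over soft-margin dual machines
solved on the precomputed Gram matrix; stored support vectors, signed dual
coefficients alpha_i y_i and the bias d reproduce every decision score as
f(x) = sum_i alpha_i y_i K(s_i, x) + d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .exceptions import ConfigError, DataError, ShapeError

MAX_QUBITS = 12  # statevector bound: 2^12 amplitudes


@dataclass
class KernelSpec:
    family: str = "polynomial"  # or "quantum_second_order"
    degree: int = 3
    scale: float = 1.0
    offset: float = 0.0
    n_qubits: int = 4
    repetitions: int = 2
    entanglement: tuple[tuple[int, int], ...] | None = None  # None = full pairwise

    def validate(self) -> None:
        if self.family not in ("polynomial", "quantum_second_order"):
            raise ConfigError(f"unknown kernel family {self.family!r}")
        if self.degree < 1:
            raise ConfigError(f"degree must be >= 1, got {self.degree}")
        if self.n_qubits < 1:
            raise ConfigError(f"n_qubits must be >= 1, got {self.n_qubits}")
        if self.repetitions < 1:
            raise ConfigError("repetitions must be >= 1")
        for i, j in self.pairs():
            if not (0 <= i < self.n_qubits and 0 <= j < self.n_qubits and i != j):
                raise ConfigError(f"invalid entanglement pair ({i},{j})")

    def pairs(self) -> tuple[tuple[int, int], ...]:
        if self.entanglement is not None:
            return tuple(self.entanglement)
        n = self.n_qubits
        return tuple((i, j) for i in range(n) for j in range(i + 1, n))


def poly_kernel(x: np.ndarray, z: np.ndarray, spec: KernelSpec) -> float:
    x, z = np.asarray(x, dtype=float), np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ShapeError(f"feature dimension mismatch: {x.shape} vs {z.shape}")
    return float((spec.scale * np.dot(x, z) + spec.offset) ** spec.degree)


def _hadamard_all(state: np.ndarray, n: int) -> np.ndarray:
    """Apply H to every qubit (normalized Walsh-Hadamard transform)."""
    s = state.reshape((2,) * n)
    for q in range(n):
        s = np.moveaxis(s, q, 0)
        a, b = s[0].copy(), s[1].copy()
        s[0] = (a + b) / np.sqrt(2.0)
        s[1] = (a - b) / np.sqrt(2.0)
        s = np.moveaxis(s, 0, q)
    return s.reshape(-1)


def _phase_table(x: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Diagonal phase angle per basis state for the Z/ZZ layer.

    Angles follow the second-order-expansion convention theta_i = x_i and
    theta_ij = (pi - x_i)(pi - x_j); ``spec.scale`` multiplies the features
    first, acting as the kernel bandwidth (scale 1.0 on [0, pi] features
    gives a highly oscillatory kernel; smaller scales smooth it).
    """
    n = spec.n_qubits
    dim = 1 << n
    x = spec.scale * x
    basis = np.arange(dim)
    # qubit 0 = most significant bit; sign s_i = +1 for bit 0, -1 for bit 1
    signs = np.empty((dim, n))
    for q in range(n):
        bits = (basis >> (n - 1 - q)) & 1
        signs[:, q] = 1.0 - 2.0 * bits
    phase = signs @ x
    for i, j in spec.pairs():
        phase += (np.pi - x[i]) * (np.pi - x[j]) * signs[:, i] * signs[:, j]
    return phase


def soe_statevector(x: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Amplitudes of [diag-phase . H^(x)n]^repetitions |0...0>."""
    spec.validate()
    x = np.asarray(x, dtype=float)
    n = spec.n_qubits
    if x.shape != (n,):
        raise ShapeError(f"feature vector must have dimension {n}, got {x.shape}")
    if n > MAX_QUBITS:
        raise ConfigError(f"n_qubits {n} exceeds statevector bound {MAX_QUBITS}")
    phases = np.exp(1j * _phase_table(x, spec))
    state = np.zeros(1 << n, dtype=complex)
    state[0] = 1.0
    for _ in range(spec.repetitions):
        state = _hadamard_all(state, n)
        state = state * phases
    return state


def quantum_kernel(x: np.ndarray, z: np.ndarray, spec: KernelSpec) -> float:
    """Fidelity kernel |<phi(x), phi(z)>|^2."""
    sx = soe_statevector(x, spec)
    sz = soe_statevector(z, spec)
    return float(np.abs(np.vdot(sx, sz)) ** 2)


def gram_matrix(X: np.ndarray, spec: KernelSpec, Z: np.ndarray | None = None) -> np.ndarray:
    """Kernel matrix K[i, j] = K(X[i], Z[j]) (Z defaults to X)."""
    spec.validate()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.isfinite(X).all():
        raise DataError("features contain non-finite values")
    sym = Z is None
    Z = X if sym else np.atleast_2d(np.asarray(Z, dtype=float))
    if not np.isfinite(Z).all():
        raise DataError("features contain non-finite values")
    if X.shape[1] != Z.shape[1]:
        raise ShapeError(f"feature dimensions differ: {X.shape[1]} vs {Z.shape[1]}")
    if spec.family == "polynomial":
        return (spec.scale * (X @ Z.T) + spec.offset) ** spec.degree
    states_x = np.stack([soe_statevector(row, spec) for row in X])
    states_z = states_x if sym else np.stack([soe_statevector(row, spec) for row in Z])
    return np.abs(states_x @ states_z.conj().T) ** 2


@dataclass
class FeatureProjection:
    """Mean-centred leading-variance projection plus [0, pi] rescale."""

    components: np.ndarray  # (n_qubits, latent_dim) orthonormal rows
    mean: np.ndarray  # (latent_dim,)
    mins: np.ndarray
    maxs: np.ndarray

    def project(self, Z: np.ndarray) -> np.ndarray:
        """Centred coordinates along the stored directions (no rescale)."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return (Z - self.mean) @ self.components.T

    def transform(self, Z: np.ndarray) -> np.ndarray:
        coords = self.project(Z)
        span = np.where(self.maxs > self.mins, self.maxs - self.mins, 1.0)
        return (coords - self.mins) / span * np.pi


def reduce_features(Z: np.ndarray, n_qubits: int) -> tuple[np.ndarray, FeatureProjection]:
    """Fit the projection on training latents; reuse for test data."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] < 2:
        raise DataError("need at least 2 samples to fit the projection")
    if Z.shape[1] < n_qubits:
        raise DataError(
            f"latent dimension {Z.shape[1]} smaller than n_qubits {n_qubits}"
        )
    pca = PCA(n_components=n_qubits, svd_solver="full")
    coords = pca.fit_transform(Z)
    proj = FeatureProjection(
        components=pca.components_.copy(),
        mean=pca.mean_.copy(),
        mins=coords.min(axis=0),
        maxs=coords.max(axis=0),
    )
    return proj.transform(Z), proj


@dataclass
class BinaryMachine:
    support_vectors: np.ndarray
    dual_coef: np.ndarray  # alpha_i * y_i at the support vectors
    bias: float
    support_labels: np.ndarray  # +-1 labels of the support vectors


@dataclass
class QsvmModel:
    machines: list[BinaryMachine]
    classes: np.ndarray
    spec: KernelSpec
    C: float
    train_features: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def fit_qsvm(X: np.ndarray, y, spec: KernelSpec, C: float = 1.0) -> QsvmModel:
    """One-vs-rest soft-margin dual machines on the precomputed Gram matrix."""
    spec.validate()
    if C <= 0:
        raise ConfigError(f"C must be > 0, got {C}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise DataError("need at least 2 classes to fit a classifier")
    G = gram_matrix(X, spec)
    min_eig = float(np.linalg.eigvalsh(G).min())
    if min_eig < -1e-8 * max(1.0, float(np.abs(G).max())):
        raise DataError(
            f"Gram matrix is not PSD (min eigenvalue {min_eig:.3e}); "
            "consider adding diagonal jitter"
        )
    machines = []
    for c in classes:
        yb = np.where(y == c, 1, -1)
        svc = SVC(C=C, kernel="precomputed")
        svc.fit(G, yb)
        sv = svc.support_
        machines.append(
            BinaryMachine(
                support_vectors=X[sv].copy(),
                dual_coef=svc.dual_coef_[0].copy(),
                bias=float(svc.intercept_[0]),
                support_labels=yb[sv].copy(),
            )
        )
    return QsvmModel(machines=machines, classes=classes, spec=spec, C=C)


def decision_scores(model: QsvmModel, X: np.ndarray) -> np.ndarray:
    """f(x) = sum_i alpha_i y_i K(s_i, x) + d for every one-vs-rest machine."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    dim = model.machines[0].support_vectors.shape[1]
    if X.shape[1] != dim:
        raise ShapeError(f"features have dimension {X.shape[1]}, model expects {dim}")
    scores = np.empty((X.shape[0], len(model.machines)))
    for k, m in enumerate(model.machines):
        K = gram_matrix(X, model.spec, m.support_vectors)
        scores[:, k] = K @ m.dual_coef + m.bias
    return scores


def predict(model: QsvmModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class labels (argmax of one-vs-rest scores; ties -> lowest class index)."""
    scores = decision_scores(model, X)
    return model.classes[scores.argmax(axis=1)], scores


def save_qsvm(model: QsvmModel, path, projection: FeatureProjection | None = None) -> None:
    """Portable array archive: support vectors, duals, bias, kernel, projection."""
    spec = model.spec
    arrays = {
        "classes": model.classes,
        "C": np.array(model.C),
        "kernel": np.array(
            [
                spec.family,
                str(spec.degree),
                str(spec.scale),
                str(spec.offset),
                str(spec.n_qubits),
                str(spec.repetitions),
            ]
        ),
        "pairs": np.array(spec.pairs(), dtype=int).reshape(-1, 2),
    }
    for k, m in enumerate(model.machines):
        arrays[f"sv_{k}"] = m.support_vectors
        arrays[f"dual_{k}"] = m.dual_coef
        arrays[f"bias_{k}"] = np.array(m.bias)
        arrays[f"ylab_{k}"] = m.support_labels
    if projection is not None:
        arrays["proj_components"] = projection.components
        arrays["proj_mean"] = projection.mean
        arrays["proj_mins"] = projection.mins
        arrays["proj_maxs"] = projection.maxs
    np.savez(path, **arrays)


def load_qsvm(path) -> tuple[QsvmModel, FeatureProjection | None]:
    with np.load(path, allow_pickle=False) as a:
        kern = [str(v) for v in a["kernel"]]
        spec = KernelSpec(
            family=kern[0],
            degree=int(kern[1]),
            scale=float(kern[2]),
            offset=float(kern[3]),
            n_qubits=int(kern[4]),
            repetitions=int(kern[5]),
            entanglement=tuple(map(tuple, a["pairs"])) if a["pairs"].size else None,
        )
        classes = a["classes"]
        machines = []
        for k in range(classes.size):
            machines.append(
                BinaryMachine(
                    support_vectors=a[f"sv_{k}"],
                    dual_coef=a[f"dual_{k}"],
                    bias=float(a[f"bias_{k}"]),
                    support_labels=a[f"ylab_{k}"],
                )
            )
        projection = None
        if "proj_components" in a:
            projection = FeatureProjection(
                components=a["proj_components"],
                mean=a["proj_mean"],
                mins=a["proj_mins"],
                maxs=a["proj_maxs"],
            )
        model = QsvmModel(
            machines=machines, classes=classes, spec=spec, C=float(a["C"])
        )
    return model, projection
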