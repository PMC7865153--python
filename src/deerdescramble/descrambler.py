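"""Lie-group descrambling of fully connected layers.

The signal space of a hidden layer has no preferred ordering: backprop
training fixes the network function but leaves each internal basis
arbitrary ("scrambled").  Descrambling searches the special orthogonal
group SO(d) for a rotation ``P`` of that basis which extremizes an
interpretability functional of the tapped intermediate signals — here,
by default, Tikhonov smoothness, the squared Frobenius norm of the second
derivative of the signal array,

    eta_T(Q) = || D P(Q) W_k F_{k-1} ... F_1 W_1 X ||_F^2 ,

with ``D`` the periodic Fourier spectral second-derivative matrix and
``P(Q) = (1 - Q)(1 + Q)^{-1}`` the Cayley transform of an antisymmetric
generator ``Q``.  The Cayley chart keeps ``P`` exactly orthogonal with
det +1 for every real antisymmetric ``Q`` (the eigenvalues of ``Q`` are
imaginary, so ``1 + Q`` is never singular), and its derivative is cheap:

    dP = -(1 + P) dQ (1 + Q)^{-1} ,

so for any functional with Euclidean gradient ``G_P`` at ``P`` the
gradient with respect to ``Q`` is ``-(1 + P)^T G_P (1 + Q)^{-T}``,
antisymmetrized onto the strictly-lower-triangular parameters actually
optimized.  Optimization is limited-memory BFGS started at Q = 0
(P = identity).

Because the objective depends on the signals only through their Gram
matrix, columns of X may be accumulated in batches of any size without
changing the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .network import ACTIVATIONS, NetworkWeights

__all__ = [
    "AntisymmetricGenerator",
    "SecondDerivativeOperator",
    "DescramblerProblem",
    "DescramblerResult",
    "DescrambleConfig",
    "cayley",
    "spectral_second_derivative",
    "tikhonov_norm",
    "intermediate_signals",
    "objective_and_gradient",
    "descramble",
    "diagonal_objectives",
    "apply_descrambler",
]

OBJECTIVES = ("tikhonov", "max_diag_sum", "max_diag_normsq", "tikhonov_plus_link")
_MAX_MODES = ("max_diag_sum", "max_diag_normsq")


@dataclass(frozen=True)
class AntisymmetricGenerator:
    """Antisymmetric d x d generator, stored as its free triangle parameters.

    The parameter vector holds the entries above the diagonal (row-major),
    so for d = 2 the single parameter q gives ``Q = [[0, q], [-q, 0]]`` and
    ``cayley(Q)`` with q = 1 is the rotation by +pi/2.
    """

    params: np.ndarray
    dim: int

    def __post_init__(self) -> None:
        params = np.asarray(self.params, dtype=float).ravel()
        object.__setattr__(self, "params", params)
        if params.size != self.dim * (self.dim - 1) // 2:
            raise ValueError("parameter count does not match dimension")

    @classmethod
    def zero(cls, dim: int) -> "AntisymmetricGenerator":
        return cls(np.zeros(dim * (dim - 1) // 2), dim)

    @classmethod
    def from_matrix(cls, q: np.ndarray) -> "AntisymmetricGenerator":
        q = np.asarray(q, dtype=float)
        if q.ndim != 2 or q.shape[0] != q.shape[1]:
            raise ValueError("generator must be square")
        if not np.array_equal(q, -q.T):
            raise ValueError("generator must be exactly antisymmetric")
        d = q.shape[0]
        return cls(_upper_params(q), d)

    @property
    def matrix(self) -> np.ndarray:
        d = self.dim
        low = np.zeros((d, d))
        low[np.tril_indices(d, -1)] = self.params
        return low.T - low


def _upper_params(matrix: np.ndarray) -> np.ndarray:
    """Free parameters of an antisymmetric matrix (entries above the diagonal)."""
    d = matrix.shape[0]
    return matrix.T[np.tril_indices(d, -1)]


@dataclass(frozen=True)
class SecondDerivativeOperator:
    """Periodic Fourier spectral second-derivative matrix on a unit interval."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if np.max(np.abs(m.sum(axis=1))) > 1e-10 * max(1.0, np.max(np.abs(m))):
            raise ValueError("second-derivative rows must sum to zero")

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


def cayley(q) -> np.ndarray:
    """Cayley transform ``P = (1 - Q)(1 + Q)^{-1}`` of an antisymmetric Q.

    The result is in SO(d); ``1 + Q`` cannot be singular for real
    antisymmetric Q, which is asserted rather than handled.  The two
    operator orders agree because both factors are rational functions
    of the same matrix.
    """
    Q = q.matrix if isinstance(q, AntisymmetricGenerator) else np.asarray(q, dtype=float)
    if not np.allclose(Q, -Q.T, atol=1e-12 * max(1.0, np.max(np.abs(Q)))):
        raise ValueError("Cayley transform requires an antisymmetric matrix")
    d = Q.shape[0]
    eye = np.eye(d)
    # solve X (1 + Q) = 1 - Q  without forming the inverse
    P = np.linalg.solve((eye + Q).T, (eye - Q).T).T
    return P


def spectral_second_derivative(d: int) -> SecondDerivativeOperator:
    """Fourier spectral second-derivative matrix on ``d`` points of a unit interval.

    Only even ``d >= 4`` is supported (the odd-grid spectral stencil has a
    different closed form and is never needed here).  The matrix is real,
    symmetric, and annihilates constants.
    """
    if d < 4 or d % 2:
        raise ValueError("spectral second derivative requires even d >= 4")
    k = np.fft.fftfreq(d, d=1.0 / d)       # integer frequencies on the unit interval
    omega2 = (2.0 * np.pi * k) ** 2
    F = np.fft.fft(np.eye(d), axis=0)
    D2 = np.real(np.fft.ifft(-omega2[:, None] * F, axis=0))
    D2 = 0.5 * (D2 + D2.T)                 # symmetrize away roundoff
    return SecondDerivativeOperator(D2)


def tikhonov_norm(V: np.ndarray, D: SecondDerivativeOperator) -> float:
    """Tikhonov smoothness ``||D V||_F^2``; additive over the columns of V."""
    V = np.asarray(V, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    if V.shape[0] != D.dim:
        raise ValueError("signal rows must match the operator dimension")
    DV = D.matrix @ V
    return float(np.sum(DV * DV))


def intermediate_signals(net: NetworkWeights, X: np.ndarray, layer_index: int,
                         tap: str) -> np.ndarray:
    """Tapped signal array at a layer: affine output (``before_activation``)
    or activation output (``after_activation``), including any descrambling
    transforms already present in the network."""
    if tap not in ("before_activation", "after_activation"):
        raise ValueError("tap must be before_activation or after_activation")
    if not 0 <= layer_index < net.n_layers:
        raise IndexError("layer index out of range")
    A = np.asarray(X, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    for k in range(layer_index):
        Z = net.weights[k] @ A + net.biases[k][:, None]
        if net.pre_undo[k] is not None:
            Z = net.pre_undo[k] @ Z
        act, _ = ACTIVATIONS[net.layer_specs[k].activation]
        A = act(Z)
        if net.post_transform[k] is not None:
            A = net.post_transform[k] @ A
    Z = net.weights[layer_index] @ A + net.biases[layer_index][:, None]
    if tap == "before_activation":
        return Z
    if net.pre_undo[layer_index] is not None:
        Z = net.pre_undo[layer_index] @ Z
    act, _ = ACTIVATIONS[net.layer_specs[layer_index].activation]
    A = act(Z)
    if net.post_transform[layer_index] is not None:
        A = net.post_transform[layer_index] @ A
    return A


@dataclass
class DescramblerProblem:
    """A descrambling task: which layer to tap, which functional to extremize."""

    net: NetworkWeights
    layer_index: int
    tap: str = "before_activation"
    objective: str = "tikhonov"
    link_weight: float = 1.0
    X: np.ndarray = None
    batch_size: int = None

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVES:
            raise ValueError(f"objective must be one of {OBJECTIVES}")
        if self.tap not in ("before_activation", "after_activation"):
            raise ValueError("tap must be before_activation or after_activation")
        if not 0 <= self.layer_index < self.net.n_layers:
            raise IndexError("layer index out of range")
        if self.link_weight < 0:
            raise ValueError("link weight must be nonnegative")
        if self.objective == "tikhonov_plus_link":
            if self.layer_index + 1 >= self.net.n_layers:
                raise ValueError("combined objective needs a downstream weight matrix")

    @property
    def dim(self) -> int:
        return self.net.layer_specs[self.layer_index].output_width


def _signal_gram(problem: DescramblerProblem) -> np.ndarray:
    """Gram matrix M M^T of the tapped signals, accumulated in column batches."""
    X = np.asarray(problem.X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    d = problem.dim
    C = np.zeros((d, d))
    batch = problem.batch_size or X.shape[1]
    for start in range(0, X.shape[1], batch):
        M = intermediate_signals(problem.net, X[:, start:start + batch],
                                 problem.layer_index, problem.tap)
        C += M @ M.T
    return C


def _problem_operators(problem: DescramblerProblem):
    """Precompute (K, C, W, sign) for the selected functional.

    Tikhonov modes reduce to eta(P) = Tr(P^T K P C) with K = D^T D and C the
    signal Gram matrix (plus, for the combined mode, the weighted Gram of the
    downstream weight rows: ||(W_{k+1} P^T) differentiated along its link
    dimension||_F^2 equals ||D P W_{k+1}^T||_F^2).  Diagonal-dominance modes
    use the weight matrix directly and are maximized (sign -1 inside the
    minimizer).
    """
    d = problem.dim
    if problem.objective in ("tikhonov", "tikhonov_plus_link"):
        D = spectral_second_derivative(d)
        K = D.matrix.T @ D.matrix
        C = _signal_gram(problem)
        if problem.objective == "tikhonov_plus_link":
            W_next = problem.net.weights[problem.layer_index + 1]
            C = C + problem.link_weight * (W_next.T @ W_next)
        return {"kind": "quadratic", "K": K, "C": C, "sign": 1.0}
    W = problem.net.weights[problem.layer_index]
    if W.shape[0] != W.shape[1]:
        raise ValueError("diagonal objectives need a square weight matrix")
    return {"kind": problem.objective, "W": W, "sign": -1.0}


def _value_and_grad_p(P: np.ndarray, ops) -> tuple:
    """Objective value and Euclidean gradient with respect to P."""
    if ops["kind"] == "quadratic":
        K, C = ops["K"], ops["C"]
        KPC = K @ P @ C
        value = float(np.sum(P * KPC))
        return value, 2.0 * KPC
    W = ops["W"]
    PW = P @ W
    if ops["kind"] == "max_diag_sum":
        return float(np.trace(PW)), W.T.copy()
    diag = np.diag(PW)
    return float(np.sum(diag * diag)), 2.0 * diag[:, None] * W.T


def _grad_q_params(G_P: np.ndarray, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Chain rule through the Cayley map onto the free triangle parameters."""
    d = Q.shape[0]
    A_T = np.linalg.solve(np.eye(d) + Q, np.eye(d)).T  # (1+Q)^{-T}
    G_Q = -(np.eye(d) + P).T @ G_P @ A_T
    return _upper_params(G_Q - G_Q.T)


def objective_and_gradient(q, problem: DescramblerProblem):
    """Value of the selected functional at ``P = cayley(q)`` and its exact
    analytic gradient as an antisymmetric matrix."""
    gen = q if isinstance(q, AntisymmetricGenerator) else AntisymmetricGenerator.from_matrix(q)
    ops = _problem_operators(problem)
    Q = gen.matrix
    P = cayley(Q)
    value, G_P = _value_and_grad_p(P, ops)
    d = Q.shape[0]
    A_T = np.linalg.solve(np.eye(d) + Q, np.eye(d)).T
    G_Q = -(np.eye(d) + P).T @ G_P @ A_T
    return value, 0.5 * (G_Q - G_Q.T)


@dataclass(frozen=True)
class DescrambleConfig:
    maxiter: int = 500
    gtol: float = 1e-8
    memory: int = 10
    ftol: float = 1e-14


@dataclass
class DescramblerResult:
    q_star: AntisymmetricGenerator
    p_star: np.ndarray
    objective_history: np.ndarray
    final_gradient_norm: float
    converged: bool


def descramble(problem: DescramblerProblem,
               config: DescrambleConfig = DescrambleConfig()) -> DescramblerResult:
    """Quasi-Newton (L-BFGS) extremization of the functional over SO(d).

    Minimizes the Tikhonov modes and maximizes the diagonal-dominance modes
    (via negation); the optimizer runs over the strictly-lower-triangular
    parameters of Q starting from Q = 0.  Non-convergence within the
    iteration cap sets ``converged=False`` rather than raising.
    """
    ops = _problem_operators(problem)
    d = problem.dim
    sign = ops["sign"]

    def fun(params):
        Q = AntisymmetricGenerator(params, d).matrix
        P = cayley(Q)
        value, G_P = _value_and_grad_p(P, ops)
        g = _grad_q_params(G_P, P, Q)
        return sign * value, sign * g

    history = []

    def cb(params):
        Q = AntisymmetricGenerator(params, d).matrix
        value, _ = _value_and_grad_p(cayley(Q), ops)
        history.append(value)

    x0 = np.zeros(d * (d - 1) // 2)
    v0, _ = fun(x0)
    history.append(sign * v0)
    res = optimize.minimize(
        fun, x0, jac=True, method="L-BFGS-B", callback=cb,
        options={"maxiter": config.maxiter, "maxcor": config.memory,
                 "gtol": config.gtol, "ftol": config.ftol},
    )
    q_star = AntisymmetricGenerator(res.x, d)
    p_star = cayley(q_star.matrix)
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success) or grad_norm <= config.gtol
    return DescramblerResult(
        q_star=q_star, p_star=p_star,
        objective_history=np.asarray(history),
        final_gradient_norm=grad_norm, converged=converged,
    )


def diagonal_objectives(q, W: np.ndarray, mode: str = "max_diag_sum") -> float:
    """Diagonal-dominance functionals at ``P = cayley(q)``:
    ``Tr(P W)`` (max diagonal sum) or ``||diag(P W)||_2^2`` (max diagonal
    norm square)."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("diagonal objectives require a square weight matrix")
    P = cayley(q)
    if P.shape[0] != W.shape[0]:
        raise ValueError("generator dimension does not match W")
    PW = P @ W
    if mode == "max_diag_sum":
        return float(np.trace(PW))
    if mode == "max_diag_normsq":
        diag = np.diag(PW)
        return float(np.sum(diag * diag))
    raise ValueError("mode must be max_diag_sum or max_diag_normsq")


def _check_orthogonal(P: np.ndarray, tol: float = 1e-6) -> None:
    err = np.linalg.norm(P @ P.T - np.eye(P.shape[0]))
    if err > tol:
        raise ValueError(f"descrambler must be orthogonal, ||PP^T - I|| = {err:.2e}")


def apply_descrambler(net: NetworkWeights, layer_index: int, tap: str,
                      P: np.ndarray) -> NetworkWeights:
    """Absorb a wiretap ``P^{-1} P`` into the network without changing its function.

    before_activation: ``W_k <- P W_k``, ``b_k <- P b_k`` and the inverse is
    recorded as an explicit pre-activation undo (the nonlinearity blocks
    absorbing it downstream).  after_activation: a post-activation transform
    ``P`` is recorded and ``P^T`` is absorbed into ``W_{k+1}`` exactly, or
    into an output-side undo when the tapped layer is the last one.
    """
    P = np.asarray(P, dtype=float)
    _check_orthogonal(P)
    if not 0 <= layer_index < net.n_layers:
        raise IndexError("layer index out of range")
    d = net.layer_specs[layer_index].output_width
    if P.shape != (d, d):
        raise ValueError("descrambler dimension does not match the tapped layer")
    out = net.copy()
    if tap == "before_activation":
        out.weights[layer_index] = P @ out.weights[layer_index]
        out.biases[layer_index] = P @ out.biases[layer_index]
        undo = out.pre_undo[layer_index]
        undo = P.T if undo is None else undo @ P.T
        if np.allclose(undo, np.eye(d), atol=1e-12):
            undo = None
        out.pre_undo[layer_index] = undo
    elif tap == "after_activation":
        post = out.post_transform[layer_index]
        post = P if post is None else P @ post
        if np.allclose(post, np.eye(d), atol=1e-12):
            post = None
        out.post_transform[layer_index] = post
        if layer_index + 1 < net.n_layers:
            out.weights[layer_index + 1] = out.weights[layer_index + 1] @ P.T
        else:
            undo = out.output_undo
            undo = P.T if undo is None else undo @ P.T
            if np.allclose(undo, np.eye(d), atol=1e-12):
                undo = None
            out.output_undo = undo
    else:
        raise ValueError("tap must be before_activation or after_activation")
    return out
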