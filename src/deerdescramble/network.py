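"""Small fully connected feed-forward networks for Fredholm inversion.

A network is the map ``y = F_n W_n F_{n-1} W_{n-1} ... F_1 W_1 x`` (biases
folded into each affine stage).  The canonical solver layout is
input > fully connected > tanh > fully connected > logistic > regression:
the hidden "sigmoidal" unit is tanh and the output "logsig" unit is the
logistic function, whose positive range matches the physical meaning of the
output (a probability density).

Training is plain backpropagation with Adam on a mean-squared-error loss,
implemented directly on numpy arrays so that every weight, bias and update
is reproducible bit-for-bit from the run seed.

Descrambled networks carry two optional per-layer linear stages produced by
:func:`deerdescramble.descrambler.apply_descrambler`: a pre-activation undo
(the explicit ``P^-1`` of a wiretap inserted before the activation) and a
post-activation transform (the ``P`` of a wiretap inserted after it).  Both
default to ``None`` and leave the network function untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ACTIVATIONS",
    "LayerSpec",
    "NetworkWeights",
    "TrainConfig",
    "TrainingError",
    "init_network",
    "forward",
    "train",
    "ensemble_train",
    "ensemble_stats",
    "rank_truncate",
]


def _tanh(z):
    return np.tanh(z)


def _tanh_deriv(a):
    return 1.0 - a * a


def _logsig(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _logsig_deriv(a):
    return a * (1.0 - a)


def _identity(z):
    return z


def _identity_deriv(a):
    return np.ones_like(a)


# activation -> (function, derivative expressed through the activation output)
ACTIVATIONS = {
    "sigmoid": (_tanh, _tanh_deriv),   # "sigmoidal" hidden unit = tanh
    "tanh": (_tanh, _tanh_deriv),
    "logsig": (_logsig, _logsig_deriv),
    "identity": (_identity, _identity_deriv),
}


@dataclass(frozen=True)
class LayerSpec:
    output_width: int
    activation: str

    def __post_init__(self) -> None:
        if self.output_width < 1:
            raise ValueError("layer width must be positive")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}; "
                             f"choose from {sorted(ACTIVATIONS)}")


@dataclass
class NetworkWeights:
    """Ordered weight matrices, biases and activation tags of an MLP."""

    weights: list
    biases: list
    layer_specs: list
    pre_undo: list = None        # optional per-layer P^T applied before the activation
    post_transform: list = None  # optional per-layer P applied after the activation
    output_undo: np.ndarray = None  # optional final undo (last-layer post tap)

    def __post_init__(self) -> None:
        n = len(self.weights)
        if not (len(self.biases) == len(self.layer_specs) == n):
            raise ValueError("weights, biases and layer_specs must align")
        for k in range(n):
            w, b, spec = self.weights[k], self.biases[k], self.layer_specs[k]
            if w.shape[0] != spec.output_width or b.shape != (w.shape[0],):
                raise ValueError(f"layer {k}: bias/width mismatch")
            if k > 0 and w.shape[1] != self.weights[k - 1].shape[0]:
                raise ValueError(f"layer {k}: input dim does not chain")
        if self.pre_undo is None:
            self.pre_undo = [None] * n
        if self.post_transform is None:
            self.post_transform = [None] * n

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[1]

    @property
    def is_plain(self) -> bool:
        return (all(m is None for m in self.pre_undo)
                and all(m is None for m in self.post_transform)
                and self.output_undo is None)

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            layer_specs=list(self.layer_specs),
            pre_undo=[None if m is None else m.copy() for m in self.pre_undo],
            post_transform=[None if m is None else m.copy() for m in self.post_transform],
            output_undo=None if self.output_undo is None else self.output_undo.copy(),
        )


def init_network(input_dim: int, layer_specs, seed: int) -> NetworkWeights:
    """Glorot-uniform initialization, biases at zero, from a single seed."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    fan_in = input_dim
    for spec in layer_specs:
        fan_out = spec.output_width
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_out, fan_in)))
        biases.append(np.zeros(fan_out))
        fan_in = fan_out
    return NetworkWeights(weights=weights, biases=biases, layer_specs=list(layer_specs))


def forward(net: NetworkWeights, X: np.ndarray) -> np.ndarray:
    """Apply the network to an array of input columns."""
    A = np.asarray(X, dtype=float)
    squeeze = A.ndim == 1
    if squeeze:
        A = A[:, None]
    if A.shape[0] != net.input_dim:
        raise ValueError(f"input rows {A.shape[0]} != network input dim {net.input_dim}")
    for k in range(net.n_layers):
        Z = net.weights[k] @ A + net.biases[k][:, None]
        if net.pre_undo[k] is not None:
            Z = net.pre_undo[k] @ Z
        act, _ = ACTIVATIONS[net.layer_specs[k].activation]
        A = act(Z)
        if net.post_transform[k] is not None:
            A = net.post_transform[k] @ A
    if net.output_undo is not None:
        A = net.output_undo @ A
    return A[:, 0] if squeeze else A


@dataclass(frozen=True)
class TrainConfig:
    loss: str = "mse"
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    validation_fraction: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.loss != "mse":
            raise ValueError("only mean squared error is supported")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0 <= self.validation_fraction < 1):
            raise ValueError("validation fraction must be in [0, 1)")


class TrainingError(RuntimeError):
    """Raised when the loss diverges; carries the epoch and last finite loss."""


def _forward_cache(net, X):
    acts = [X]
    A = X
    for k in range(net.n_layers):
        Z = net.weights[k] @ A + net.biases[k][:, None]
        act, _ = ACTIVATIONS[net.layer_specs[k].activation]
        A = act(Z)
        acts.append(A)
    return acts


def _backprop(net, acts, Y):
    """Gradients of mean over all output elements of (pred - Y)^2."""
    n_out, n_cols = Y.shape
    scale = 2.0 / (n_out * n_cols)
    delta = scale * (acts[-1] - Y)
    grads_w, grads_b = [None] * net.n_layers, [None] * net.n_layers
    for k in range(net.n_layers - 1, -1, -1):
        _, deriv = ACTIVATIONS[net.layer_specs[k].activation]
        delta = delta * deriv(acts[k + 1])
        grads_w[k] = delta @ acts[k].T
        grads_b[k] = delta.sum(axis=1)
        if k > 0:
            delta = net.weights[k].T @ delta
    return grads_w, grads_b


def train(net: NetworkWeights, dataset, cfg: TrainConfig):
    """Train a copy of ``net`` by Adam on MSE; returns (trained_net, history).

    ``dataset`` is either a :class:`~deerdescramble.forward_model.Dataset`
    or an ``(X, Y)`` tuple of column-sample arrays.  History is a dict with
    per-epoch ``train_loss`` and (if a validation split is held out)
    ``val_loss`` arrays.
    """
    if not net.is_plain:
        raise ValueError("training expects a plain (non-descrambled) network")
    if hasattr(dataset, "inputs"):
        X, Y = dataset.inputs, dataset.targets
    else:
        X, Y = dataset
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != net.input_dim:
        raise ValueError("dataset input dim does not match network")
    n_samples = X.shape[1]
    rng = np.random.default_rng(cfg.rng_seed)
    perm = rng.permutation(n_samples)
    n_val = int(round(cfg.validation_fraction * n_samples))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xt, Yt = X[:, train_idx], Y[:, train_idx]
    Xv, Yv = X[:, val_idx], Y[:, val_idx]

    out = net.copy()
    m_w = [np.zeros_like(w) for w in out.weights]
    v_w = [np.zeros_like(w) for w in out.weights]
    m_b = [np.zeros_like(b) for b in out.biases]
    v_b = [np.zeros_like(b) for b in out.biases]
    step = 0
    train_hist, val_hist = [], []
    n_train = Xt.shape[1]
    batch = min(cfg.batch_size, n_train)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_train)
        for start in range(0, n_train, batch):
            idx = order[start:start + batch]
            acts = _forward_cache(out, Xt[:, idx])
            gw, gb = _backprop(out, acts, Yt[:, idx])
            step += 1
            bc1 = 1.0 - cfg.beta1**step
            bc2 = 1.0 - cfg.beta2**step
            for k in range(out.n_layers):
                for g, m, v, p in ((gw[k], m_w[k], v_w[k], out.weights[k]),
                                   (gb[k], m_b[k], v_b[k], out.biases[k])):
                    m *= cfg.beta1
                    m += (1 - cfg.beta1) * g
                    v *= cfg.beta2
                    v += (1 - cfg.beta2) * g * g
                    p -= cfg.learning_rate * (m / bc1) / (np.sqrt(v / bc2) + cfg.eps)
        pred = forward(out, Xt)
        loss = float(np.mean((pred - Yt) ** 2))
        if not np.isfinite(loss):
            raise TrainingError(f"loss diverged at epoch {epoch} "
                                f"(last finite: {train_hist[-1] if train_hist else None})")
        train_hist.append(loss)
        if n_val:
            val_hist.append(float(np.mean((forward(out, Xv) - Yv) ** 2)))
    history = {"train_loss": np.array(train_hist)}
    if n_val:
        history["val_loss"] = np.array(val_hist)
        pred_v = forward(out, Xv)
        history["val_nrmse"] = float(np.linalg.norm(pred_v - Yv)
                                     / max(np.linalg.norm(Yv), 1e-300))
    return out, history


def _member_seed(base_seed: int, member: int) -> int:
    return int(np.random.SeedSequence([base_seed, member]).generate_state(1)[0] % (2**31))


def ensemble_train(dataset, cfg: TrainConfig, n_nets: int, input_dim: int, layer_specs):
    """Train ``n_nets`` independently initialized members; seeds derive from cfg."""
    if n_nets < 1:
        raise ValueError("need at least one ensemble member")
    nets = []
    for i in range(n_nets):
        seed = _member_seed(cfg.rng_seed, i)
        member = init_network(input_dim, layer_specs, seed)
        try:
            trained, _ = train(member, dataset, replace(cfg, rng_seed=seed))
        except TrainingError as err:
            raise TrainingError(f"ensemble member {i}: {err}") from err
        nets.append(trained)
    return nets


def ensemble_stats(nets, trace_values, quantiles=(0.0, 1.0)):
    """Pointwise mean and quantile band of ensemble outputs on one input.

    Returns ``(mean, lower, upper)``; the default band is min/max.
    """
    if len(nets) < 2:
        warnings.warn("single-member ensemble: spread band is degenerate")
    outputs = np.column_stack([forward(net, np.asarray(trace_values, dtype=float))
                               for net in nets])
    mean = outputs.mean(axis=1)
    lower = np.quantile(outputs, quantiles[0], axis=1)
    upper = np.quantile(outputs, quantiles[1], axis=1)
    return mean, lower, upper


def rank_truncate(net: NetworkWeights, layer_index: int, rank: int = None,
                  tol: float = None) -> NetworkWeights:
    """Reduce the link dimension entering layer ``layer_index`` to rank ``r``.

    The layer's weight matrix is factored through its SVD and split into a
    rank-r linear compression ``sqrt(S_r) V_r^T`` (identity activation, no
    bias) followed by an expansion ``U_r sqrt(S_r)`` carrying the original
    bias and activation, so the network gains one layer and the new link
    dimension is ``r``.  At full rank the outputs are unchanged; otherwise
    the end-to-end perturbation is bounded by the discarded singular values
    times the downstream Lipschitz constants.
    """
    if not net.is_plain:
        raise ValueError("rank truncation expects a plain network")
    if not 0 <= layer_index < net.n_layers:
        raise IndexError("layer index out of range")
    W = net.weights[layer_index]
    U, s, Vt = np.linalg.svd(W, full_matrices=False)
    if rank is None:
        if tol is None:
            raise ValueError("give either rank or tol")
        rank = max(1, int(np.sum(s > tol * s[0])))
    if not 1 <= rank <= len(s):
        raise ValueError(f"rank must be in [1, {len(s)}]")
    root = np.sqrt(s[:rank])
    compress = root[:, None] * Vt[:rank]          # r x in
    expand = U[:, :rank] * root[None, :]          # out x r
    weights = (net.weights[:layer_index]
               + [compress, expand]
               + net.weights[layer_index + 1:])
    biases = (net.biases[:layer_index]
              + [np.zeros(rank), net.biases[layer_index].copy()]
              + net.biases[layer_index + 1:])
    specs = (net.layer_specs[:layer_index]
             + [LayerSpec(rank, "identity"), net.layer_specs[layer_index]]
             + net.layer_specs[layer_index + 1:])
    return NetworkWeights(weights=[w.copy() for w in weights],
                          biases=[b.copy() for b in biases],
                          layer_specs=specs)
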