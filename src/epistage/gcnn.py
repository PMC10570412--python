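"""Chebyshev graph-convolutional classifier for three-stage EEG staging.

The network follows the ChebNet construction: spectral graph filters are
Chebyshev polynomials ``T_k`` of the rescaled normalized Laplacian, so a
K-order filter mixes information from nodes up to K-1 hops apart. The
architecture is two convolution blocks (graph convolution -> max pool ->
ReLU), a flatten, two fully connected layers with ReLU + dropout between
them, and a softmax output over the three stages:

    input [B, 1, 8, 5]
    block 1: ChebConv(1 -> 10) -> pool (nodes 8->4, features 5->3) -> ReLU
    block 2: ChebConv(10 -> 20) -> pool (nodes 4->2, features 3->1) -> ReLU
    flatten [B, 40] -> FC(40 -> 15) -> ReLU -> dropout -> FC(15 -> 3) -> softmax

Convolution acts along the node axis, independently for each position on the
feature axis (filter weights are shared across feature positions). Node
pooling merges the fixed pairs (2k, 2k+1) — on a uniform complete graph all
pairings are equivalent, so a fixed one keeps the model deterministic; the
coarsened graph is again complete. Feature-axis pooling uses left-aligned
windows with the last window absorbing the remainder (5->3: |0|1|234|,
3->1: |012|).

Everything is plain NumPy with hand-written backpropagation; a
finite-difference gradient check in the test suite guards the derivatives.
Training is mini-batch SGD with momentum on the cross-entropy loss.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .graphs import DatasetSplit, GraphSample, complete_adjacency

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainHistory",
    "GCNNModel",
    "scaled_laplacian",
    "cheb_conv",
    "train_model",
    "predict",
]


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class ModelConfig:
    """Architecture parameters (defaults give the 8-channel, 5-feature model)."""

    n_nodes: int = 8
    in_feature_len: int = 5
    block_channels: tuple[int, int] = (10, 20)
    cheb_order: int = 3
    fc_hidden: int = 15
    n_classes: int = 3
    dropout_rate: float = 0.5
    pooled_nodes: tuple[int, int] = (4, 2)
    pooled_features: tuple[int, int] = (3, 1)

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.cheb_order < 1:
            raise ValueError("cheb_order must be >= 1")

    @property
    def flatten_len(self) -> int:
        return (
            self.block_channels[1] * self.pooled_nodes[1] * self.pooled_features[1]
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (SGD with momentum on cross-entropy)."""

    learning_rate: float = 0.001
    epochs: int = 50
    batch_size_train: int = 6
    momentum: float = 0.5
    log_interval: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "epochs", "batch_size_train", "log_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")


@dataclass
class TrainHistory:
    """Per-training-epoch loss/accuracy curves."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# graph operators

def scaled_laplacian(adjacency: np.ndarray) -> np.ndarray:
    """Rescaled normalized Laplacian ``2 L_norm / lambda_max - I``.

    ``L_norm = D^{-1/2} (D - A) D^{-1/2}`` with the convention that an
    isolated node contributes a zero row (its degree is replaced by 1 in the
    normalization, with a warning). The spectrum of the result lies in
    [-1, 1]. If the Laplacian is identically zero (fully degenerate graph),
    ``lambda_max`` falls back to the theoretical bound 2, giving ``-I``.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if (A < 0).any():
        raise ValueError("adjacency must be non-negative")
    deg = A.sum(axis=1)
    if (deg == 0).any():
        warnings.warn(
            "isolated node(s) in adjacency; degree treated as 1",
            RuntimeWarning,
            stacklevel=2,
        )
    dhat = np.where(deg == 0, 1.0, deg)
    dinv = 1.0 / np.sqrt(dhat)
    L = np.diag(deg) - A
    Lnorm = dinv[:, None] * L * dinv[None, :]
    lmax = float(np.linalg.eigvalsh(Lnorm).max())
    if lmax < 1e-12:
        lmax = 2.0
    return 2.0 * Lnorm / lmax - np.eye(A.shape[0])


def chebyshev_basis(L: np.ndarray, K: int) -> np.ndarray:
    """Stack ``[T_0(L), ..., T_{K-1}(L)]`` via the Chebyshev recurrence."""
    n = L.shape[0]
    T = np.empty((K, n, n))
    T[0] = np.eye(n)
    if K > 1:
        T[1] = L
    for k in range(2, K):
        T[k] = 2.0 * L @ T[k - 1] - T[k - 2]
    return T


def cheb_conv(x: np.ndarray, L: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Chebyshev graph convolution along the node axis.

    ``x``: [batch, in_ch, nodes, feat]; ``weights``: [K, in_ch, out_ch].
    Returns ``sum_k T_k(L) x W_k`` with shape [batch, out_ch, nodes, feat];
    each position on the trailing feature axis is filtered independently.
    """
    x = np.asarray(x, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if x.ndim != 4:
        raise ValueError("x must be [batch, in_ch, nodes, feat]")
    K, in_ch, _ = weights.shape
    if x.shape[1] != in_ch:
        raise ValueError(f"x has {x.shape[1]} input channels, weights expect {in_ch}")
    if L.shape[0] != x.shape[2]:
        raise ValueError("Laplacian size does not match node count")
    T = chebyshev_basis(L, K)
    z = np.einsum("kij,bcjf->kbcif", T, x)
    return np.einsum("kbcif,kco->boif", z, weights)


# ---------------------------------------------------------------------------
# layers (forward + backward)

def _pool_windows(n_in: int, n_out: int) -> list[tuple[int, int]]:
    """Left-aligned equal windows; the last absorbs the remainder."""
    w = n_in // n_out
    if w < 1:
        raise ValueError(f"cannot pool {n_in} positions to {n_out}")
    bounds = [(i * w, (i + 1) * w) for i in range(n_out - 1)]
    bounds.append(((n_out - 1) * w, n_in))
    return bounds


class _ChebConvLayer:
    def __init__(self, in_ch: int, out_ch: int, K: int, L: np.ndarray, rng):
        bound = 1.0 / np.sqrt(K * in_ch)
        self.W = rng.uniform(-bound, bound, size=(K, in_ch, out_ch))
        self.b = np.zeros(out_ch)
        self.T = chebyshev_basis(L, K)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._z = np.einsum("kij,bcjf->kbcif", self.T, x)
        return (
            np.einsum("kbcif,kco->boif", self._z, self.W)
            + self.b[None, :, None, None]
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = np.einsum("kbcif,boif->kco", self._z, dy)
        self.db = dy.sum(axis=(0, 2, 3))
        u = np.einsum("boif,kco->kbcif", dy, self.W)
        # T_k symmetric (polynomials of a symmetric matrix)
        return np.einsum("kij,kbcif->bcjf", self.T, u)

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.dW, self.db]


class _MaxPoolLayer:
    """Target-size max pooling over the node axis then the feature axis."""

    def __init__(self, nodes_out: int, feat_out: int):
        self.nodes_out = nodes_out
        self.feat_out = feat_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, N, F = x.shape
        if N % 2 != 0 and self.nodes_out == N // 2:
            raise ValueError("node axis must have even length for pair pooling")
        node_w = _pool_windows(N, self.nodes_out)
        feat_w = _pool_windows(F, self.feat_out)
        out = np.empty((B, C, self.nodes_out, self.feat_out))
        self._argmax = np.empty((B, C, self.nodes_out, self.feat_out, 2), dtype=int)
        for ni, (n0, n1) in enumerate(node_w):
            for fi, (f0, f1) in enumerate(feat_w):
                window = x[:, :, n0:n1, f0:f1].reshape(B, C, -1)
                flat_idx = window.argmax(axis=2)
                out[:, :, ni, fi] = np.take_along_axis(
                    window, flat_idx[:, :, None], axis=2
                )[:, :, 0]
                self._argmax[:, :, ni, fi, 0] = n0 + flat_idx // (f1 - f0)
                self._argmax[:, :, ni, fi, 1] = f0 + flat_idx % (f1 - f0)
        self._in_shape = x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._in_shape)
        B, C, NO, FO = dy.shape
        bi, ci = np.meshgrid(np.arange(B), np.arange(C), indexing="ij")
        for ni in range(NO):
            for fi in range(FO):
                rows = self._argmax[:, :, ni, fi, 0]
                cols = self._argmax[:, :, ni, fi, 1]
                np.add.at(dx, (bi, ci, rows, cols), dy[:, :, ni, fi])
        return dx


class _ReLULayer:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class _DropoutLayer:
    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x: np.ndarray, training: bool, rng) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class _LinearLayer:
    def __init__(self, n_in: int, n_out: int, rng):
        bound = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.dW, self.db]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model

class GCNNModel:
    """The two-block Chebyshev GCNN classifier."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        L1 = scaled_laplacian(complete_adjacency(c.n_nodes))
        L2 = scaled_laplacian(complete_adjacency(c.pooled_nodes[0]))
        self.conv1 = _ChebConvLayer(1, c.block_channels[0], c.cheb_order, L1, rng)
        self.pool1 = _MaxPoolLayer(c.pooled_nodes[0], c.pooled_features[0])
        self.relu1 = _ReLULayer()
        self.conv2 = _ChebConvLayer(
            c.block_channels[0], c.block_channels[1], c.cheb_order, L2, rng
        )
        self.pool2 = _MaxPoolLayer(c.pooled_nodes[1], c.pooled_features[1])
        self.relu2 = _ReLULayer()
        self.fc1 = _LinearLayer(c.flatten_len, c.fc_hidden, rng)
        self.relu3 = _ReLULayer()
        self.dropout = _DropoutLayer(c.dropout_rate)
        self.fc2 = _LinearLayer(c.fc_hidden, c.n_classes, rng)
        self.trained = False

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c = self.config
        if x.ndim != 4 or x.shape[1:] != (1, c.n_nodes, c.in_feature_len):
            raise ValueError(
                f"expected input [B, 1, {c.n_nodes}, {c.in_feature_len}], "
                f"got {x.shape}"
            )
        return x

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
        shapes: Optional[list] = None,
    ) -> np.ndarray:
        """Class probabilities [B, n_classes]; rows sum to 1.

        ``shapes``, if given, collects (layer name, output shape) pairs.
        """
        x = self._check_input(x)
        if training and rng is None:
            rng = np.random.default_rng()

        def rec(name, t):
            if shapes is not None:
                shapes.append((name, tuple(t.shape)))
            return t

        h = rec("input", x)
        h = rec("gconv1", self.conv1.forward(h))
        h = rec("pool1", self.pool1.forward(h))
        h = rec("relu1", self.relu1.forward(h))
        h = rec("gconv2", self.conv2.forward(h))
        h = rec("pool2", self.pool2.forward(h))
        h = rec("relu2", self.relu2.forward(h))
        h = rec("flatten", h.reshape(h.shape[0], -1))
        self._flat_shape = None
        h = rec("fc1", self.fc1.forward(h))
        h = rec("relu3", self.relu3.forward(h))
        h = rec("dropout", self.dropout.forward(h, training, rng))
        logits = rec("fc2", self.fc2.forward(h))
        probs = rec("softmax", _softmax(logits))
        self._probs = probs
        return probs

    def loss_and_backward(self, x: np.ndarray, y: np.ndarray, rng) -> float:
        """Mean cross-entropy on a batch; fills all layer gradients."""
        y = np.asarray(y, dtype=int)
        probs = self.forward(x, training=True, rng=rng)
        B = len(y)
        eps = 1e-12
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + eps)))
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        g = self.fc2.backward(dlogits)
        g = self.dropout.backward(g)
        g = self.relu3.backward(g)
        g = self.fc1.backward(g)
        c = self.config
        g = g.reshape(
            -1, c.block_channels[1], c.pooled_nodes[1], c.pooled_features[1]
        )
        g = self.relu2.backward(g)
        g = self.pool2.backward(g)
        g = self.conv2.backward(g)
        g = self.relu1.backward(g)
        g = self.pool1.backward(g)
        self.conv1.backward(g)
        return loss

    def eval_loss(self, x: np.ndarray, y: np.ndarray) -> float:
        probs = self.forward(x, training=False)
        eps = 1e-12
        return float(-np.mean(np.log(probs[np.arange(len(y)), np.asarray(y)] + eps)))

    # -- parameters ----------------------------------------------------------

    def _layers_with_params(self):
        return [
            ("conv1", self.conv1),
            ("conv2", self.conv2),
            ("fc1", self.fc1),
            ("fc2", self.fc2),
        ]

    def parameters(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for lname, layer in self._layers_with_params():
            for pname, arr in layer.params():
                out.append((f"{lname}.{pname}", arr))
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for _, layer in self._layers_with_params():
            out.extend(layer.grads())
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: arr.copy() for name, arr in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, arr in self.parameters():
            arr[...] = state[name]

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Key-value weight archive (.npz) with the config stored as JSON."""
        payload = {k.replace(".", "__"): v for k, v in self.state_dict().items()}
        payload["__config__"] = np.array(
            json.dumps(
                {
                    k: list(v) if isinstance(v, tuple) else v
                    for k, v in vars(self.config).items()
                }
            )
        )
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "GCNNModel":
        data = np.load(path, allow_pickle=False)
        cfg_raw = json.loads(str(data["__config__"]))
        cfg = ModelConfig(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in cfg_raw.items()
            }
        )
        model = cls(cfg)
        state = {
            k.replace("__", "."): data[k] for k in data.files if k != "__config__"
        }
        model.load_state_dict(state)
        model.trained = True
        return model


# ---------------------------------------------------------------------------
# training / inference

def _stack_features(samples: list[GraphSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.node_features for s in samples])[:, None, :, :]
    y = np.array([s.label for s in samples], dtype=int)
    return x, y


def train_model(
    split: DatasetSplit,
    mcfg: ModelConfig = ModelConfig(),
    tcfg: TrainConfig = TrainConfig(),
    logger=None,
) -> tuple[GCNNModel, TrainHistory]:
    """Mini-batch SGD with momentum; returns the validation-best model state.

    Deterministic for a fixed ``tcfg.seed``: initialization, batch order and
    dropout masks all derive from it.
    """
    if not split.train or not split.validation:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(tcfg.seed)
    model = GCNNModel(mcfg, seed=int(rng.integers(2**31)))
    x_tr, y_tr = _stack_features(split.train)
    x_va, y_va = _stack_features(split.validation)

    velocity = [np.zeros_like(arr) for _, arr in model.parameters()]
    history = TrainHistory()
    best_acc = -1.0
    best_state = model.state_dict()

    n = len(y_tr)
    for ep in range(tcfg.epochs):
        order = rng.permutation(n)
        batch_losses = []
        for bstart in range(0, n, tcfg.batch_size_train):
            idx = order[bstart : bstart + tcfg.batch_size_train]
            loss = model.loss_and_backward(x_tr[idx], y_tr[idx], rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {ep}, batch "
                    f"{bstart // tcfg.batch_size_train}"
                )
            batch_losses.append(loss)
            for vel, (_, arr), grad in zip(
                velocity, model.parameters(), model.gradients()
            ):
                vel *= tcfg.momentum
                vel -= tcfg.learning_rate * grad
                arr += vel
            b_i = bstart // tcfg.batch_size_train
            if logger is not None and b_i % tcfg.log_interval == 0:
                logger.debug(
                    "epoch %d batch %d loss %.4f", ep, b_i, loss
                )
        val_probs = model.forward(x_va, training=False)
        val_pred = val_probs.argmax(axis=1)
        val_acc = float((val_pred == y_va).mean())
        val_loss = model.eval_loss(x_va, y_va)
        history.train_loss.append(float(np.mean(batch_losses)))
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        if logger is not None:
            logger.info(
                "epoch %d: train loss %.4f, val loss %.4f, val acc %.4f",
                ep,
                history.train_loss[-1],
                val_loss,
                val_acc,
            )
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    model.trained = True
    return model, history


def predict(
    model: GCNNModel, samples: list[GraphSample]
) -> tuple[np.ndarray, np.ndarray]:
    """Class indices and probabilities for a list of samples (dropout off)."""
    if not model.trained:
        raise RuntimeError("model has not been trained")
    x, _ = _stack_features(samples)
    probs = model.forward(x, training=False)
    return probs.argmax(axis=1), probs
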