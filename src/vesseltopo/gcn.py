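"""Spectral graph convolution layers and the two-layer node classifier.

The production path is the first-order propagation Y = S X Theta with
S = D_hat^(-1/2) (A + I) D_hat^(-1/2); a Chebyshev-polynomial layer of
arbitrary order K is provided for comparison, evaluated with the recurrence
T_k = 2 L_hat T_{k-1} - T_{k-2} on the rescaled Laplacian
L_hat = (2 / lambda_max) L - I,  L = I - D^(-1/2) A D^(-1/2).

The classifier stacks two first-order layers (C -> H' -> num_classes) with
a rectifier and dropout between them and a per-node softmax on top, trained
full-batch with cross-entropy and Adam.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import scipy.sparse as sp

from . import _nn
from ._nn import Tensor
from .graph import VesselGraph, NormalizedAdjacency, normalize
from .synth import NUM_CLASSES


@dataclass
class GCNParams:
    """Weights of the two-layer node classifier (plus optional input scaler)."""

    Theta1: np.ndarray  # (C, H')
    Theta2: np.ndarray  # (H', num_classes)
    dropout_rate: float = 0.5
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.Theta1)) and np.all(np.isfinite(self.Theta2))):
            raise ValueError("parameters must be finite")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def hidden_width(self) -> int:
        return self.Theta1.shape[1]


@dataclass
class ChebParams:
    """Coefficients of a K-th order Chebyshev filter."""

    K: int
    theta_k: list[np.ndarray]  # K + 1 matrices, each (C, F)
    lambda_max: float = 2.0

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("Chebyshev order K must be >= 0")
        if len(self.theta_k) != self.K + 1:
            raise ValueError(
                f"need K + 1 = {self.K + 1} coefficient matrices, got {len(self.theta_k)}"
            )


@dataclass(frozen=True)
class GCNTrainConfig:
    learning_rate: float = 0.003
    lr_decay_factor: float = 0.01
    lr_decay_interval: int = 30
    total_epochs: int = 200
    hidden_width: int = 32
    dropout_rate: float = 0.5
    loss_on_vessel_nodes_only: bool = False
    standardize_features: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_epochs < 0:
            raise ValueError("total_epochs must be >= 0")
        if not 0.0 < self.lr_decay_factor <= 1.0:
            raise ValueError("lr_decay_factor must be in (0, 1]")


def gcn_layer(X: np.ndarray, S: sp.spmatrix, Theta: np.ndarray) -> np.ndarray:
    """First-order spectral convolution: Y = S X Theta via sparse propagation."""
    X = np.asarray(X, dtype=np.float64)
    Theta = np.asarray(Theta, dtype=np.float64)
    if S.shape[0] != S.shape[1] or S.shape[1] != X.shape[0]:
        raise ValueError(f"S {S.shape} does not conform with X {X.shape}")
    if X.shape[1] != Theta.shape[0]:
        raise ValueError(f"X {X.shape} does not conform with Theta {Theta.shape}")
    return S @ (X @ Theta)


def _sym_norm_halves(A: sp.spmatrix) -> sp.dia_matrix:
    """D^(-1/2) with the convention that zero-degree entries map to 0."""
    deg = np.asarray(A.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv = 1.0 / np.sqrt(deg)
    inv[~np.isfinite(inv)] = 0.0
    return sp.diags(inv)

def laplacian(A: sp.spmatrix) -> sp.csr_matrix:
    """Symmetric normalized Laplacian L = I - D^(-1/2) A D^(-1/2).

    Zero-degree nodes get D^(-1/2) entry 0, so L acts as the identity there.
    """
    A = sp.csr_matrix(A, dtype=np.float64)
    Dinv = _sym_norm_halves(A)
    n = A.shape[0]
    return (sp.identity(n, format="csr") - Dinv @ A @ Dinv).tocsr()


def cheb_layer(X: np.ndarray, A: sp.spmatrix, params: ChebParams) -> np.ndarray:
    """Chebyshev-filtered convolution: sum_k T_k(L_hat) X theta_k."""
    X = np.asarray(X, dtype=np.float64)
    L = laplacian(A)
    n = L.shape[0]
    if X.shape[0] != n:
        raise ValueError(f"X has {X.shape[0]} rows but graph has {n} nodes")
    L_hat = (2.0 / params.lambda_max) * L - sp.identity(n, format="csr")
    t_prev = X  # T_0(L_hat) X
    Y = t_prev @ params.theta_k[0]
    if params.K >= 1:
        t_curr = L_hat @ X  # T_1(L_hat) X
        Y = Y + t_curr @ params.theta_k[1]
        for k in range(2, params.K + 1):
            t_next = 2.0 * (L_hat @ t_curr) - t_prev
            Y = Y + t_next @ params.theta_k[k]
            t_prev, t_curr = t_curr, t_next
    return Y


def first_order_identity_check(
    A: sp.spmatrix, x: np.ndarray, theta: np.ndarray, tol: float = 1e-10
) -> bool:
    """Check the shared-parameter collapse of the K=1 Chebyshev filter.

    With theta = theta0 = -theta1, verifies
    theta0 x - theta1 D^(-1/2) A D^(-1/2) x == theta (I + D^(-1/2) A D^(-1/2)) x.
    Requires an invertible degree matrix (no isolated nodes).
    """
    A = sp.csr_matrix(A, dtype=np.float64)
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg == 0):
        raise ValueError("graph has isolated nodes; degree matrix not invertible")
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[0] != A.shape[0]:
        x = x.T
    theta = np.atleast_2d(np.asarray(theta, dtype=np.float64))
    Dinv = sp.diags(1.0 / np.sqrt(deg))
    SA = Dinv @ A @ Dinv
    theta0 = theta
    theta1 = -theta
    lhs = x @ theta0 - (SA @ x) @ theta1
    rhs = (x + SA @ x) @ theta
    return bool(np.max(np.abs(lhs - rhs)) <= tol)


def _apply_scaler(X: np.ndarray, params: GCNParams) -> np.ndarray:
    if params.feature_mean is None:
        return X
    return (X - params.feature_mean) / params.feature_scale


def forward(
    graph: VesselGraph | np.ndarray,
    S: sp.spmatrix | NormalizedAdjacency,
    params: GCNParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Two-layer node classifier; returns per-node class probabilities.

    Inference (training=False) is deterministic: dropout is applied only in
    training mode (an rng is then required).
    """
    X = graph.X if isinstance(graph, VesselGraph) else np.asarray(graph)
    Smat = S.S if isinstance(S, NormalizedAdjacency) else S
    X = _apply_scaler(np.asarray(X, dtype=np.float64), params)
    h = gcn_layer(X, Smat, params.Theta1)
    h = np.maximum(h, 0.0)
    if training and params.dropout_rate > 0.0:
        if rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        mask = (rng.random(h.shape) >= params.dropout_rate) / (1.0 - params.dropout_rate)
        h = h * mask
    logits = gcn_layer(h, Smat, params.Theta2)
    return _nn.softmax(logits)


def init_params(
    num_features: int,
    config: GCNTrainConfig,
    num_classes: int = NUM_CLASSES,
) -> GCNParams:
    """Glorot-uniform initialization, deterministic in the config seed."""
    rng = np.random.default_rng(config.seed)

    def glorot(cin: int, cout: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (cin + cout))
        return rng.uniform(-limit, limit, size=(cin, cout))

    return GCNParams(
        Theta1=glorot(num_features, config.hidden_width),
        Theta2=glorot(config.hidden_width, num_classes),
        dropout_rate=config.dropout_rate,
    )


def learning_rate_at(config: GCNTrainConfig, epoch: int) -> float:
    """Scheduled learning rate for a 0-based epoch index."""
    return config.learning_rate * config.lr_decay_factor ** (
        epoch // config.lr_decay_interval
    )


def train_gcn(
    graphs: list[VesselGraph],
    config: GCNTrainConfig,
    num_classes: int = NUM_CLASSES,
    progress: bool = False,
) -> tuple[GCNParams, list[dict]]:
    """Full-batch training over labeled graphs (one graph per gradient step).

    Cross-entropy over all nodes by default (isolated background nodes carry
    the background label); ``loss_on_vessel_nodes_only`` restricts the loss
    to nodes with at least one edge.  Node features are standardized with
    training-set statistics stored in the returned params.
    """
    if not graphs:
        raise ValueError("need at least one training graph")
    for g in graphs:
        if g.y is None:
            raise ValueError("every training graph needs node labels")
    num_features = graphs[0].X.shape[1]
    params = init_params(num_features, config, num_classes)

    if config.standardize_features:
        allX = np.concatenate([g.X for g in graphs], axis=0)
        params.feature_mean = allX.mean(axis=0)
        params.feature_scale = allX.std(axis=0) + 1e-8

    prepared = []
    for g in graphs:
        S = normalize(g.A).S
        Xs = _apply_scaler(g.X.astype(np.float64), params)
        wts = None
        if config.loss_on_vessel_nodes_only:
            deg = np.asarray(g.A.sum(axis=1)).ravel()
            wts = (deg > 0).astype(np.float64)
        prepared.append((Xs, S, g.y, wts))

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    t1 = Tensor(params.Theta1, requires_grad=True, dtype=np.float64)
    t2 = Tensor(params.Theta2, requires_grad=True, dtype=np.float64)
    opt = _nn.Adam([t1, t2], lr=config.learning_rate)
    history: list[dict] = []
    for epoch in range(config.total_epochs):
        lr = learning_rate_at(config, epoch)
        opt.lr = lr
        losses = []
        for Xs, S, y, wts in prepared:
            x = Tensor(Xs, dtype=np.float64)
            h = _nn.relu(_nn.spmm(S, _nn.matmul(x, t1)))
            h = _nn.dropout(h, config.dropout_rate, rng)
            logits = _nn.spmm(S, _nn.matmul(h, t2))
            loss, _ = _nn.softmax_cross_entropy(logits, y, weights=wts)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite GCN loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append({"epoch": epoch, "loss": float(np.mean(losses)), "lr": lr})
        if progress and epoch % 20 == 0:
            print(f"[gcn] epoch {epoch} loss {history[-1]['loss']:.4f}")
    params.Theta1 = t1.data
    params.Theta2 = t2.data
    return params, history


def predict(graph: VesselGraph, params: GCNParams) -> np.ndarray:
    """Inference on one graph; returns (N, num_classes) probabilities."""
    S = normalize(graph.A).S
    return forward(graph, S, params, training=False)


def save_params(params: GCNParams, config: GCNTrainConfig, path) -> None:
    arrays = {"Theta1": params.Theta1, "Theta2": params.Theta2}
    if params.feature_mean is not None:
        arrays["feature_mean"] = params.feature_mean
        arrays["feature_scale"] = params.feature_scale
    meta = {"dropout_rate": params.dropout_rate, "config": asdict(config)}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_params(path) -> tuple[GCNParams, GCNTrainConfig]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = GCNParams(
            Theta1=data["Theta1"],
            Theta2=data["Theta2"],
            dropout_rate=meta["dropout_rate"],
            feature_mean=data["feature_mean"] if "feature_mean" in data else None,
            feature_scale=data["feature_scale"] if "feature_scale" in data else None,
        )
    return params, GCNTrainConfig(**meta["config"])
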