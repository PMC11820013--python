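"""Cascaded spatial/channel attention MIL model (CAMIL).

The model classifies a *bag* — a slide's N x C_in matrix of patch feature
vectors — into a binary slide label, with no instance-level supervision.
The pipeline is

    encoder -> cascaded attention block -> decoder -> attention pooling -> FC

where the cascaded block composes two self-attention refinements of the
instance feature matrix ``X`` (N instances, C channels):

Spatial (instance-to-instance) attention
    A = X W_A + b_A,  B = X W_B + b_B                  (two projections)
    S[i, j] = softmax_i( A_i . B_j )                   (N x N, columns sum to 1)
    E_j     = alpha * sum_i S[i, j] D_i + X_j          (D = X W_D + b_D)

Channel (feature-to-feature) attention
    M = E^T E                                          (C x C channel Gram)
    Cmat[i, j] = softmax_i( M[i, j] )                  (columns sum to 1)
    G[:, j]    = beta * sum_i Cmat[i, j] E[:, i] + E[:, j]

``alpha`` and ``beta`` are learnable scalars initialized to exactly zero,
so at initialization both residual blocks are the identity and the whole
model coincides with a plain attention-pooling MIL classifier sharing the
remaining weights.  Both softmaxes are max-stabilized per column, which is
exact by shift invariance; the raw dot products are NOT scaled by 1/sqrt(C).

Five fusion modes select how the two modules combine (the default,
spatial -> channel, performed best in ablation); ``"none"`` disables the
block entirely and yields the plain attention-MIL baseline.

Everything runs in float64 on the CPU via the in-package autodiff tape.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data_model import Bag

FUSION_MODES = (
    "spatial_then_channel",
    "channel_then_spatial",
    "spatial_only",
    "channel_only",
    "parallel_concat",
    "none",
)


# --------------------------------------------------------------------------
# Baseline aggregators of the classical MIL formulation
# --------------------------------------------------------------------------


def mil_bag_label(instance_labels) -> int:
    """Standard MIL assumption: the bag is positive iff any instance is."""
    labels = np.asarray(instance_labels)
    if labels.size == 0:
        raise ValueError("empty instance label vector")
    return int(labels.any())


def max_aggregate(instance_scores) -> float:
    """Max-pooling aggregation: the bag score is the highest instance score."""
    scores = np.asarray(instance_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty instance score vector")
    return float(scores.max())


def mean_aggregate(instance_scores) -> float:
    """Mean-pooling aggregation baseline."""
    scores = np.asarray(instance_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty instance score vector")
    return float(scores.mean())


# --------------------------------------------------------------------------
# Configuration and parameters
# --------------------------------------------------------------------------


@dataclass
class CamilConfig:
    """Architecture hyperparameters.

    ``in_dim`` is the stored feature dimensionality (512 for the CNN
    features the pipeline produces by default); ``model_dim`` the internal
    width shared by the encoder output, attention block and decoder;
    ``pool_hidden`` the hidden width of the tanh attention-pooling scorer.
    """

    in_dim: int = 512
    model_dim: int = 256
    pool_hidden: int = 128
    fusion_mode: str = "spatial_then_channel"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fusion_mode not in FUSION_MODES:
            raise ValueError(f"unknown fusion mode {self.fusion_mode!r}; options: {FUSION_MODES}")
        if min(self.in_dim, self.model_dim, self.pool_hidden) < 1:
            raise ValueError("all dimensions must be >= 1")


def init_params(config: CamilConfig) -> Dict[str, np.ndarray]:
    """Seeded Glorot-normal initialization.

    ``alpha`` and ``beta`` start at exactly 0 so the attention block is the
    identity at initialization.  The classifier weights start at 0, making
    the untrained output probability exactly 0.5.
    """
    rng = np.random.default_rng(config.seed)
    ci, cm, hp = config.in_dim, config.model_dim, config.pool_hidden

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        std = np.sqrt(2.0 / (fan_in + fan_out))
        return rng.normal(0.0, std, size=(fan_in, fan_out))

    return {
        "enc_W": glorot(ci, cm),
        "enc_b": np.zeros(cm),
        "W_A": glorot(cm, cm),
        "b_A": np.zeros(cm),
        "W_B": glorot(cm, cm),
        "b_B": np.zeros(cm),
        "W_D": glorot(cm, cm),
        "b_D": np.zeros(cm),
        "alpha": np.zeros(()),
        "beta": np.zeros(()),
        "concat_W": glorot(2 * cm, cm),
        "concat_b": np.zeros(cm),
        "dec_W": glorot(cm, cm),
        "dec_b": np.zeros(cm),
        "pool_V": glorot(cm, hp),
        "pool_bV": np.zeros(hp),
        "pool_w": glorot(hp, 1),
        "pool_bw": np.zeros(()),
        "cls_W": np.zeros((cm, 1)),
        "cls_b": np.zeros(()),
    }


@dataclass
class BagPrediction:
    """Model output for one bag."""

    prob: float
    logit: float
    instance_weights: np.ndarray


# --------------------------------------------------------------------------
# Functional attention operations (NumPy in / NumPy out)
# --------------------------------------------------------------------------


def spatial_projections(
    X: np.ndarray, params: Dict[str, np.ndarray]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Affine projections A, B, D of the instance matrix (bias per row)."""
    X = np.asarray(X, dtype=np.float64)
    A = X @ params["W_A"] + params["b_A"]
    B = X @ params["W_B"] + params["b_B"]
    D = X @ params["W_D"] + params["b_D"]
    return A, B, D


def spatial_attention_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-stochastic N x N spatial attention matrix.

    ``S[i, j]`` is the influence of instance i on instance j:
    softmax over i of the similarity A_i . B_j, max-stabilized per column.
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.shape != B.shape:
        raise ValueError(f"A and B must share a shape, got {A.shape} vs {B.shape}")
    logits = A @ B.T  # logits[i, j] = A_i . B_j
    logits = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=0, keepdims=True)


def apply_spatial_attention(
    S: np.ndarray, D: np.ndarray, X: np.ndarray, alpha: float
) -> np.ndarray:
    """Residual spatial refinement: E_j = alpha * sum_i S[i,j] D_i + X_j."""
    S = np.asarray(S, dtype=np.float64)
    D = np.asarray(D, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    if S.shape != (X.shape[0], X.shape[0]) or D.shape != X.shape:
        raise ValueError("inconsistent shapes in spatial attention application")
    return float(alpha) * (S.T @ D) + X


def channel_attention_matrix(E: np.ndarray) -> np.ndarray:
    """Column-stochastic C x C channel attention matrix.

    Logits are the channel Gram matrix E^T E (dot products of feature
    columns); the softmax runs over the influencing channel i for each
    target channel j, max-stabilized.
    """
    E = np.asarray(E, dtype=np.float64)
    if E.ndim != 2 or E.shape[1] < 1:
        raise ValueError("E must be a non-empty N x C matrix")
    logits = E.T @ E
    logits = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=0, keepdims=True)


def apply_channel_attention(Cmat: np.ndarray, E: np.ndarray, beta: float) -> np.ndarray:
    """Residual channel refinement: G[:,j] = beta * sum_i Cmat[i,j] E[:,i] + E[:,j]."""
    Cmat = np.asarray(Cmat, dtype=np.float64)
    E = np.asarray(E, dtype=np.float64)
    if Cmat.shape != (E.shape[1], E.shape[1]):
        raise ValueError("channel matrix shape inconsistent with E")
    return float(beta) * (E @ Cmat) + E


def _spatial_block(X: np.ndarray, params: Dict[str, np.ndarray]) -> np.ndarray:
    A, B, D = spatial_projections(X, params)
    S = spatial_attention_matrix(A, B)
    return apply_spatial_attention(S, D, X, float(params["alpha"]))


def _channel_block(X: np.ndarray, params: Dict[str, np.ndarray]) -> np.ndarray:
    Cmat = channel_attention_matrix(X)
    return apply_channel_attention(Cmat, X, float(params["beta"]))


def cascaded_block(
    X: np.ndarray, params: Dict[str, np.ndarray], fusion_mode: str = "spatial_then_channel"
) -> np.ndarray:
    """Apply the attention block under the requested fusion strategy."""
    X = np.asarray(X, dtype=np.float64)
    if fusion_mode == "spatial_then_channel":
        return _channel_block(_spatial_block(X, params), params)
    if fusion_mode == "channel_then_spatial":
        return _spatial_block(_channel_block(X, params), params)
    if fusion_mode == "spatial_only":
        return _spatial_block(X, params)
    if fusion_mode == "channel_only":
        return _channel_block(X, params)
    if fusion_mode == "parallel_concat":
        both = np.concatenate([_spatial_block(X, params), _channel_block(X, params)], axis=1)
        return both @ params["concat_W"] + params["concat_b"]
    if fusion_mode == "none":
        return X
    raise ValueError(f"unknown fusion mode {fusion_mode!r}")


def attention_pool(
    H: np.ndarray, params: Dict[str, np.ndarray]
) -> Tuple[np.ndarray, np.ndarray]:
    """Attention pooling: softmax-weighted average of instance embeddings.

    Scores come from a two-layer tanh scorer; returns (bag_vector, weights)
    with weights nonnegative and summing to 1.
    """
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError("attention_pool requires a non-empty N x C matrix")
    scores = np.tanh(H @ params["pool_V"] + params["pool_bV"]) @ params["pool_w"]
    scores = scores[:, 0] + float(params["pool_bw"])
    scores = scores - scores.max()
    w = np.exp(scores)
    w = w / w.sum()
    return w @ H, w


def forward(bag: Union[Bag, np.ndarray], params: Dict[str, np.ndarray],
            fusion_mode: str = "spatial_then_channel") -> BagPrediction:
    """Full inference pass for one bag; deterministic."""
    X = bag.X if isinstance(bag, Bag) else bag
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != params["enc_W"].shape[0]:
        raise ValueError(
            f"bag has {X.shape[1]} channels but the model expects {params['enc_W'].shape[0]}"
        )
    Z = np.maximum(X @ params["enc_W"] + params["enc_b"], 0.0)
    H = cascaded_block(Z, params, fusion_mode)
    Dc = np.maximum(H @ params["dec_W"] + params["dec_b"], 0.0)
    bag_vec, w = attention_pool(Dc, params)
    logit = float(bag_vec @ params["cls_W"][:, 0] + params["cls_b"])
    prob = float(1.0 / (1.0 + np.exp(-logit)))
    return BagPrediction(prob=prob, logit=logit, instance_weights=w)


# --------------------------------------------------------------------------
# Differentiable graph (training / attribution path)
# --------------------------------------------------------------------------


def _graph_spatial(X: Tensor, p: Dict[str, Tensor]) -> Tensor:
    A = X @ p["W_A"] + p["b_A"]
    B = X @ p["W_B"] + p["b_B"]
    D = X @ p["W_D"] + p["b_D"]
    S = ad.softmax_columns(A @ B.T)
    return p["alpha"] * (S.T @ D) + X


def _graph_channel(X: Tensor, p: Dict[str, Tensor]) -> Tensor:
    Cmat = ad.softmax_columns(X.T @ X)
    return p["beta"] * (X @ Cmat) + X


def build_graph(
    X: np.ndarray, p: Dict[str, Tensor], fusion_mode: str
) -> Tuple[Tensor, Tensor, Dict[str, Tensor]]:
    """Build the differentiable forward graph for one bag.

    Returns ``(logit, weights, nodes)`` where ``nodes`` exposes the named
    intermediate tensors (encoder / attention / decoder outputs) for
    gradient-based attribution.
    """
    Xt = Tensor(np.asarray(X, dtype=np.float64))
    Z = ad.relu(Xt @ p["enc_W"] + p["enc_b"])
    if fusion_mode == "spatial_then_channel":
        H = _graph_channel(_graph_spatial(Z, p), p)
    elif fusion_mode == "channel_then_spatial":
        H = _graph_spatial(_graph_channel(Z, p), p)
    elif fusion_mode == "spatial_only":
        H = _graph_spatial(Z, p)
    elif fusion_mode == "channel_only":
        H = _graph_channel(Z, p)
    elif fusion_mode == "parallel_concat":
        both = ad.concat([_graph_spatial(Z, p), _graph_channel(Z, p)], axis=1)
        H = both @ p["concat_W"] + p["concat_b"]
    elif fusion_mode == "none":
        H = Z
    else:
        raise ValueError(f"unknown fusion mode {fusion_mode!r}")
    Dc = ad.relu(H @ p["dec_W"] + p["dec_b"])
    scores = ad.tanh(Dc @ p["pool_V"] + p["pool_bV"]) @ p["pool_w"] + p["pool_bw"]
    w = ad.softmax_columns(scores)  # N x 1 column softmax over instances
    bag_vec = w.T @ Dc  # 1 x C
    logit = ad.tsum(bag_vec @ p["cls_W"]) + p["cls_b"]
    nodes = {"encoder": Z, "attention": H, "decoder": Dc, "weights": w}
    return logit, w, nodes


def bce_loss(logit: Tensor, y: int) -> Tensor:
    """Binary cross-entropy on the bag logit, numerically stable."""
    return ad.softplus(logit) - float(y) * logit


class CamilModel:
    """Stateful wrapper bundling a config, its parameters and (de)serialization."""

    def __init__(self, config: CamilConfig, params: Optional[Dict[str, np.ndarray]] = None):
        self.config = config
        self.params = params if params is not None else init_params(config)

    # -- inference -------------------------------------------------------
    def predict(self, bag: Union[Bag, np.ndarray]) -> BagPrediction:
        return forward(bag, self.params, self.config.fusion_mode)

    def predict_proba(self, bags) -> np.ndarray:
        return np.array([self.predict(b).prob for b in bags])

    # -- training --------------------------------------------------------
    def _param_tensors(self) -> Dict[str, Tensor]:
        return {k: Tensor(v, requires_grad=True) for k, v in self.params.items()}

    def loss_and_grads(
        self, X: np.ndarray, y: int
    ) -> Tuple[float, Dict[str, np.ndarray]]:
        """One-bag loss and analytic gradients for every parameter."""
        p = self._param_tensors()
        logit, _, _ = build_graph(X, p, self.config.fusion_mode)
        loss = bce_loss(logit, y)
        loss.backward()
        grads = {
            k: (t.grad if t.grad is not None else np.zeros_like(self.params[k]))
            for k, t in p.items()
        }
        return float(loss.data), grads

    def clone_params(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    # -- checkpoint ------------------------------------------------------
    def save(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        cfg_json = json.dumps(asdict(self.config))
        np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
                 **self.params)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "CamilModel":
        with np.load(Path(path)) as data:
            if "__config__" not in data:
                raise ValueError(f"{path}: not a model checkpoint (missing config block)")
            cfg = CamilConfig(**json.loads(bytes(data["__config__"]).decode()))
            params = {k: np.array(data[k]) for k in data.files if k != "__config__"}
        expected = set(init_params(cfg))
        if set(params) != expected:
            raise ValueError(
                f"{path}: checkpoint parameter set mismatch "
                f"(missing {sorted(expected - set(params))}, "
                f"extra {sorted(set(params) - expected)})"
            )
        ref = init_params(cfg)
        for k, v in params.items():
            if v.shape != ref[k].shape:
                raise ValueError(f"{path}: parameter {k} has shape {v.shape}, expected {ref[k].shape}")
        return cls(cfg, params)
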