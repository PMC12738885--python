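"""Interpretable two-layer graph convolutional classifier.

Architecture, for one sample with feature vector x over the universal gene
list G and a fixed region graph with normalized adjacency A_hat:

    H0   node features: softplus(gamma) ⊙ x broadcast to every node
         (optionally masked to each region's own DEG set)
    H1 = ELU(A_hat H0 Θ1)          (dropout after H1 during training)
    H2 = ELU(A_hat H1 Θ2)
    L  = LayerNorm(H2) per node, scaled per node by softplus(rho)
    z  = mean over nodes of L       (global mean pooling)
    ŷ  = softmax(W_c z + b_c)

gamma (one entry per gene) and rho (one entry per region) are trainable
importance gates; because they enter multiplicatively through a softplus,
their fitted magnitudes read directly as gene and region importances.

Everything is plain numpy.  The backward pass is written analytically and is
verified against finite differences in the test suite; training loops live in
:mod:`degbrin.traineval`.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

_SOFTPLUS_ONE = float(np.log(np.e - 1.0))  # raw gate value with softplus(.) = 1
LN_EPS = 1e-5
PROB_FLOOR = 1e-12

CLASSES = ("CON", "MCI", "AD")


@dataclass(frozen=True)
class GCNConfig:
    """Shape and regularization of the classifier."""

    n_nodes: int
    in_dim: int
    hidden_dim: int = 103
    n_classes: int = 3
    dropout: float = 0.458
    feature_mode: str = "broadcast"  # broadcast | masked | per_node
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_nodes", "in_dim", "hidden_dim", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.feature_mode not in ("broadcast", "masked", "per_node"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")


PARAM_KEYS = ("theta1", "theta2", "ln_scale", "ln_shift", "wc", "bc", "gamma", "rho")


@dataclass
class GCNParams:
    """Trainable parameters; ``gamma``/``rho`` are raw gate values (pre-softplus)."""

    theta1: np.ndarray
    theta2: np.ndarray
    ln_scale: np.ndarray
    ln_shift: np.ndarray
    wc: np.ndarray
    bc: np.ndarray
    gamma: np.ndarray
    rho: np.ndarray

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in PARAM_KEYS}

    def copy(self) -> "GCNParams":
        return GCNParams(**{k: v.copy() for k, v in self.as_dict().items()})

    def flatten(self) -> np.ndarray:
        return np.concatenate([getattr(self, k).ravel() for k in PARAM_KEYS])


def softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x):
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


def _glorot(rng, fan_in, fan_out, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(config: GCNConfig) -> GCNParams:
    """Glorot-uniform weights, zero biases, gates neutral (softplus = 1)."""
    rng = np.random.default_rng(config.seed)
    h, f, c = config.hidden_dim, config.in_dim, config.n_classes
    return GCNParams(
        theta1=_glorot(rng, f, h, (f, h)),
        theta2=_glorot(rng, h, h, (h, h)),
        ln_scale=np.ones(h),
        ln_shift=np.zeros(h),
        wc=_glorot(rng, h, c, (c, h)),
        bc=np.zeros(c),
        gamma=np.full(f, _SOFTPLUS_ONE),
        rho=np.full(config.n_nodes, _SOFTPLUS_ONE),
    )


@dataclass
class GraphBatch:
    """A batch of samples sharing one normalized adjacency.

    x has shape (B, in_dim) for broadcast/masked feature modes or
    (B, n_nodes, in_dim) for per_node mode; ``mask`` is an optional
    (n_nodes, in_dim) binary matrix zeroing genes absent from each node's
    region DEG set.
    """

    a_hat: np.ndarray
    x: np.ndarray
    labels: np.ndarray | None = None  # integer class indices
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.x)):
            raise ValueError("non-finite values in batch features")
        if not np.allclose(self.a_hat, self.a_hat.T):
            raise ValueError("a_hat must be symmetric")


def _node_features(params: GCNParams, batch: GraphBatch, mode: str) -> np.ndarray:
    g = softplus(params.gamma)
    if mode == "per_node":
        if batch.x.ndim != 3:
            raise ValueError("per_node mode expects x of shape (B, n_nodes, in_dim)")
        return batch.x * g[None, None, :]
    if batch.x.ndim != 2:
        raise ValueError(f"{mode} mode expects x of shape (B, in_dim)")
    h0 = np.broadcast_to(
        (batch.x * g[None, :])[:, None, :],
        (batch.x.shape[0], batch.a_hat.shape[0], batch.x.shape[1]),
    ).copy()
    if mode == "masked":
        if batch.mask is None:
            raise ValueError("masked mode requires batch.mask")
        h0 *= batch.mask[None, :, :]
    return h0


def forward(
    params: GCNParams,
    batch: GraphBatch,
    config: GCNConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
    return_cache: bool = False,
):
    """Class probabilities (B, n_classes); with ``return_cache`` also the
    intermediates needed by :func:`backward`."""
    a = batch.a_hat
    h0 = _node_features(params, batch, config.feature_mode)
    s1 = np.matmul(a, h0)
    z1 = s1 @ params.theta1
    h1 = elu(z1)
    if training and config.dropout > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        keep = 1.0 - config.dropout
        drop = (rng.random(h1.shape) < keep) / keep
    else:
        drop = None
    h1d = h1 if drop is None else h1 * drop
    s2 = np.matmul(a, h1d)
    z2 = s2 @ params.theta2
    h2 = elu(z2)
    mu = h2.mean(axis=-1, keepdims=True)
    var = h2.var(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + LN_EPS)
    hn = (h2 - mu) * inv_std
    ln = hn * params.ln_scale + params.ln_shift
    r = softplus(params.rho)
    pooled_in = ln * r[None, :, None]
    z = pooled_in.mean(axis=1)
    logits = z @ params.wc.T + params.bc
    logits = logits - logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    probs = expl / expl.sum(axis=1, keepdims=True)
    if not return_cache:
        return probs
    cache = dict(
        h0=h0, s1=s1, z1=z1, h1=h1, drop=drop, s2=s2, z2=z2, h2=h2,
        inv_std=inv_std, hn=hn, ln=ln, r=r, z=z, probs=probs,
    )
    return probs, cache


def loss(probs: np.ndarray, labels) -> float:
    """Mean cross-entropy −log p[label] with probability floor 1e−12."""
    probs = np.atleast_2d(probs)
    labels = np.atleast_1d(labels)
    picked = probs[np.arange(len(labels)), labels]
    return float(-np.log(np.maximum(picked, PROB_FLOOR)).mean())


def backward(
    params: GCNParams,
    batch: GraphBatch,
    config: GCNConfig,
    cache: dict,
    return_input_grads: bool = False,
):
    """Analytic gradients of the mean cross-entropy w.r.t. every parameter block.

    Returns a dict keyed like :data:`PARAM_KEYS`; with ``return_input_grads``
    also d(loss)/d(x) for gradient-weighted importances.
    """
    a = batch.a_hat
    B = cache["probs"].shape[0]
    n = a.shape[0]
    labels = np.asarray(batch.labels)
    dlogits = cache["probs"].copy()
    dlogits[np.arange(B), labels] -= 1.0
    dlogits /= B

    grads: dict = {}
    grads["wc"] = dlogits.T @ cache["z"]
    grads["bc"] = dlogits.sum(axis=0)
    dz = dlogits @ params.wc  # (B, h)
    dpooled = np.repeat(dz[:, None, :], n, axis=1) / n
    dln = dpooled * cache["r"][None, :, None]
    grads["rho"] = np.einsum(
        "bnh,bnh->n", dpooled, cache["ln"]
    ) * _sigmoid(params.rho)
    grads["ln_scale"] = np.einsum("bnh,bnh->h", dln, cache["hn"])
    grads["ln_shift"] = dln.sum(axis=(0, 1))
    dhn = dln * params.ln_scale
    # layer-norm backward over the hidden axis
    h = dhn.shape[-1]
    dh2 = cache["inv_std"] * (
        dhn
        - dhn.mean(axis=-1, keepdims=True)
        - cache["hn"] * (dhn * cache["hn"]).mean(axis=-1, keepdims=True)
    )
    dz2 = dh2 * _elu_grad(cache["z2"])
    grads["theta2"] = cache["s2"].reshape(-1, cache["s2"].shape[-1]).T @ dz2.reshape(-1, dz2.shape[-1])
    ds2 = dz2 @ params.theta2.T
    dh1d = np.matmul(a.T, ds2)
    dh1 = dh1d if cache["drop"] is None else dh1d * cache["drop"]
    dz1 = dh1 * _elu_grad(cache["z1"])
    grads["theta1"] = cache["s1"].reshape(-1, cache["s1"].shape[-1]).T @ dz1.reshape(-1, dz1.shape[-1])
    ds1 = dz1 @ params.theta1.T
    dh0 = np.matmul(a.T, ds1)

    g = softplus(params.gamma)
    sg = _sigmoid(params.gamma)
    if config.feature_mode == "per_node":
        grads["gamma"] = np.einsum("bnf,bnf->f", dh0, batch.x) * sg
        dx = dh0 * g[None, None, :] if return_input_grads else None
    else:
        eff = dh0 if batch.mask is None or config.feature_mode != "masked" else dh0 * batch.mask[None, :, :]
        grads["gamma"] = np.einsum("bnf,bf->f", eff, batch.x) * sg
        dx = eff.sum(axis=1) * g[None, :] if return_input_grads else None
    if return_input_grads:
        return grads, dx
    return grads


# ---------------------------------------------------------------------------
# checkpoint serialization: one zip of .npy arrays + config JSON

def save_checkpoint(path, params: GCNParams, config: GCNConfig, extra: dict | None = None) -> None:
    path = Path(path)
    with zipfile.ZipFile(path, "w") as zf:
        for key, arr in params.as_dict().items():
            with zf.open(f"{key}.npy", "w") as fh:
                np.save(fh, arr)
        zf.writestr("config.json", json.dumps(asdict(config)))
        if extra:
            zf.writestr("extra.json", json.dumps(extra))


def load_checkpoint(path) -> tuple[GCNParams, GCNConfig, dict]:
    with zipfile.ZipFile(Path(path)) as zf:
        arrays = {}
        for key in PARAM_KEYS:
            with zf.open(f"{key}.npy") as fh:
                arrays[key] = np.load(fh)
        config = GCNConfig(**json.loads(zf.read("config.json")))
        extra = json.loads(zf.read("extra.json")) if "extra.json" in zf.namelist() else {}
    return GCNParams(**arrays), config, extra
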