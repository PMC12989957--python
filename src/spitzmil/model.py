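"""Permutation-invariant transformer aggregator for bags of tile features.

A case is a variable-size, unordered bag of tile feature vectors. The
aggregator projects each vector to the embedding space, prepends a
learnable class token, runs two pre-norm transformer blocks (multi-head
self-attention + MLP, no positional embeddings, so the model is exactly
permutation-invariant), and classifies from the final class-token
representation. Defaults follow the study architecture: embedding
dimension 192, depth 2, 4 heads, MLP ratio 4, attention dropout 0.5 and
tile (feature-vector) dropout 0.5 during training, and a hard cap of
25,000 feature vectors per forward pass.

The network and its backward pass are implemented directly in NumPy: with
a batch size of one case and an embedding width of 192 the model is small
enough that explicit gradients are simpler to audit than a framework graph,
and the whole pipeline stays CPU-only.

The per-tile attention map is the head-averaged class-token attention of
the final block, renormalized to sum to one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

__all__ = [
    "ModelConfig",
    "AggregatorState",
    "PredictionOutput",
    "init_model",
    "forward",
    "extract_attention",
    "embed_case",
    "loss_and_grads",
    "softmax",
    "save_checkpoint",
    "load_checkpoint",
]

_LN_EPS = 1e-5
_SQRT2 = np.float32(np.sqrt(2.0))
_INV_SQRT2PI = np.float32(1.0 / np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class ModelConfig:
    encoder_dim: int = 1024
    embed_dim: int = 192
    depth: int = 2
    heads: int = 4
    mlp_ratio: int = 4
    n_classes: int = 2
    attn_dropout_p: float = 0.5
    feature_dropout_p: float = 0.5
    max_features: int = 25_000

    def __post_init__(self) -> None:
        if self.embed_dim % self.heads != 0:
            raise ValueError("embed_dim must be divisible by heads")
        for name in ("attn_dropout_p", "feature_dropout_p"):
            p = getattr(self, name)
            if not (0.0 <= p < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.encoder_dim <= 0 or self.n_classes < 2:
            raise ValueError("encoder_dim must be positive and n_classes >= 2")


@dataclass
class AggregatorState:
    params: dict  # name -> float32 ndarray
    config: ModelConfig
    seed: int


@dataclass(frozen=True)
class PredictionOutput:
    logits: np.ndarray  # (n_classes,)
    probabilities: np.ndarray  # (n_classes,), softmax of logits
    attention: np.ndarray  # (n_tiles_used,), nonnegative, sums to 1
    embedding: np.ndarray  # (embed_dim,), pre-head class-token representation


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def init_model(config: ModelConfig, seed: int = 0) -> AggregatorState:
    """Random initialization (Gaussian std 0.02 weights, zero biases)."""
    rng = np.random.default_rng(seed)
    e, c = config.embed_dim, config.n_classes
    hdim = config.mlp_ratio * e

    def w(*shape):
        return (rng.standard_normal(shape) * 0.02).astype(np.float32)

    p: dict[str, np.ndarray] = {
        "proj_w": w(config.encoder_dim, e),
        "proj_b": np.zeros(e, np.float32),
        "cls": w(e),
        "lnf_g": np.ones(e, np.float32),
        "lnf_b": np.zeros(e, np.float32),
        "head_w": w(e, c),
        "head_b": np.zeros(c, np.float32),
    }
    for b in range(config.depth):
        p[f"b{b}_ln1_g"] = np.ones(e, np.float32)
        p[f"b{b}_ln1_b"] = np.zeros(e, np.float32)
        p[f"b{b}_qkv_w"] = w(e, 3 * e)
        p[f"b{b}_qkv_b"] = np.zeros(3 * e, np.float32)
        p[f"b{b}_attn_out_w"] = w(e, e)
        p[f"b{b}_attn_out_b"] = np.zeros(e, np.float32)
        p[f"b{b}_ln2_g"] = np.ones(e, np.float32)
        p[f"b{b}_ln2_b"] = np.zeros(e, np.float32)
        p[f"b{b}_mlp1_w"] = w(e, hdim)
        p[f"b{b}_mlp1_b"] = np.zeros(hdim, np.float32)
        p[f"b{b}_mlp2_w"] = w(hdim, e)
        p[f"b{b}_mlp2_b"] = np.zeros(e, np.float32)
    return AggregatorState(params=p, config=config, seed=seed)


# ---------------------------------------------------------------------------
# Layer primitives with explicit backward passes.


def _ln_fwd(x, g, b):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return xhat * g + b, (xhat, inv, g)


def _ln_bwd(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(0)
    db = dy.sum(0)
    dxhat = dy * g
    m1 = dxhat.mean(-1, keepdims=True)
    m2 = (dxhat * xhat).mean(-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def _gelu_fwd(x):
    phi = 0.5 * (1.0 + erf(x / _SQRT2))
    return x * phi, (x, phi)


def _gelu_bwd(dy, cache):
    x, phi = cache
    pdf = np.exp(-0.5 * x * x) * _INV_SQRT2PI
    return dy * (phi + x * pdf)


def _select_tiles(x: np.ndarray, config: ModelConfig, training: bool,
                  rng: np.random.Generator | None) -> np.ndarray:
    """Apply the feature-vector cap and (in training) tile dropout.

    Returns the indices of the tiles consumed by the forward pass, in their
    original order.
    """
    n = x.shape[0]
    idx = np.arange(n)
    if n > config.max_features:
        if rng is None:
            rng = np.random.default_rng(0)
        idx = np.sort(rng.choice(n, size=config.max_features, replace=False))
    if training and config.feature_dropout_p > 0.0:
        if rng is None:
            raise ValueError("training-mode forward requires an rng")
        keep = rng.random(idx.size) >= config.feature_dropout_p
        if not keep.any():
            keep[rng.integers(idx.size)] = True
        idx = idx[keep]
    return idx


def _forward(params, x, config: ModelConfig, training: bool,
             rng: np.random.Generator | None):
    """Forward pass on the (already selected) tiles; returns logits + cache."""
    e, h = config.embed_dim, config.heads
    dh = e // h
    scale = 1.0 / np.sqrt(dh)

    proj = x @ params["proj_w"] + params["proj_b"]  # (T, E)
    tokens = np.concatenate([params["cls"][None, :], proj], axis=0)  # (N, E)
    n = tokens.shape[0]

    cache = {"x": x, "blocks": [], "n": n}
    for b in range(config.depth):
        pre = tokens
        y, ln1c = _ln_fwd(tokens, params[f"b{b}_ln1_g"], params[f"b{b}_ln1_b"])
        qkv = y @ params[f"b{b}_qkv_w"] + params[f"b{b}_qkv_b"]  # (N, 3E)
        q, k, v = np.split(qkv, 3, axis=1)
        # (H, N, dh)
        q = q.reshape(n, h, dh).transpose(1, 0, 2)
        k = k.reshape(n, h, dh).transpose(1, 0, 2)
        v = v.reshape(n, h, dh).transpose(1, 0, 2)
        scores = (q @ k.transpose(0, 2, 1)) * scale
        attn = softmax(scores, axis=-1)  # (H, N, N)
        if training and config.attn_dropout_p > 0.0:
            if rng is None:
                raise ValueError("training-mode forward requires an rng")
            mask = (rng.random(attn.shape) >= config.attn_dropout_p).astype(np.float32)
            attn_used = attn * mask / (1.0 - config.attn_dropout_p)
        else:
            mask = None
            attn_used = attn
        z = attn_used @ v  # (H, N, dh)
        z_flat = z.transpose(1, 0, 2).reshape(n, e)
        attn_out = z_flat @ params[f"b{b}_attn_out_w"] + params[f"b{b}_attn_out_b"]
        tokens = pre + attn_out

        pre2 = tokens
        y2, ln2c = _ln_fwd(tokens, params[f"b{b}_ln2_g"], params[f"b{b}_ln2_b"])
        h1 = y2 @ params[f"b{b}_mlp1_w"] + params[f"b{b}_mlp1_b"]
        a1, geluc = _gelu_fwd(h1)
        mlp_out = a1 @ params[f"b{b}_mlp2_w"] + params[f"b{b}_mlp2_b"]
        tokens = pre2 + mlp_out

        cache["blocks"].append(
            dict(
                ln1c=ln1c, y=y, q=q, k=k, v=v, attn=attn, mask=mask,
                attn_used=attn_used, z_flat=z_flat,
                ln2c=ln2c, y2=y2, geluc=geluc, a1=a1,
            )
        )

    final, lnfc = _ln_fwd(tokens, params["lnf_g"], params["lnf_b"])
    embedding = final[0]
    logits = embedding @ params["head_w"] + params["head_b"]
    cache["lnfc"] = lnfc
    cache["embedding"] = embedding
    cache["final_shape"] = final.shape
    return logits, cache


def _backward(dlogits, params, cache, config: ModelConfig) -> dict:
    e, h = config.embed_dim, config.heads
    n = cache["n"]
    dh = e // h
    scale = 1.0 / np.sqrt(dh)
    g: dict[str, np.ndarray] = {}

    g["head_w"] = np.outer(cache["embedding"], dlogits)
    g["head_b"] = dlogits
    dfinal = np.zeros(cache["final_shape"], np.float32)
    dfinal[0] = dlogits @ params["head_w"].T
    dtokens, g["lnf_g"], g["lnf_b"] = _ln_bwd(dfinal, cache["lnfc"])

    for b in reversed(range(config.depth)):
        c = cache["blocks"][b]
        # MLP sub-block.
        dmlp_out = dtokens
        g[f"b{b}_mlp2_w"] = c["a1"].T @ dmlp_out
        g[f"b{b}_mlp2_b"] = dmlp_out.sum(0)
        da1 = dmlp_out @ params[f"b{b}_mlp2_w"].T
        dh1 = _gelu_bwd(da1, c["geluc"])
        g[f"b{b}_mlp1_w"] = c["y2"].T @ dh1
        g[f"b{b}_mlp1_b"] = dh1.sum(0)
        dy2 = dh1 @ params[f"b{b}_mlp1_w"].T
        dpre2, g[f"b{b}_ln2_g"], g[f"b{b}_ln2_b"] = _ln_bwd(dy2, c["ln2c"])
        dtokens = dtokens + dpre2

        # Attention sub-block.
        dattn_out = dtokens
        g[f"b{b}_attn_out_w"] = c["z_flat"].T @ dattn_out
        g[f"b{b}_attn_out_b"] = dattn_out.sum(0)
        dz_flat = dattn_out @ params[f"b{b}_attn_out_w"].T
        dz = dz_flat.reshape(n, h, dh).transpose(1, 0, 2)  # (H, N, dh)
        dattn_used = dz @ c["v"].transpose(0, 2, 1)
        dv = c["attn_used"].transpose(0, 2, 1) @ dz
        if c["mask"] is not None:
            dattn = dattn_used * c["mask"] / (1.0 - config.attn_dropout_p)
        else:
            dattn = dattn_used
        a = c["attn"]
        dscores = a * (dattn - (dattn * a).sum(-1, keepdims=True))
        dq = (dscores @ c["k"]) * scale
        dk = (dscores.transpose(0, 2, 1) @ c["q"]) * scale
        dqkv = np.concatenate(
            [
                dq.transpose(1, 0, 2).reshape(n, e),
                dk.transpose(1, 0, 2).reshape(n, e),
                dv.transpose(1, 0, 2).reshape(n, e),
            ],
            axis=1,
        )
        g[f"b{b}_qkv_w"] = c["y"].T @ dqkv
        g[f"b{b}_qkv_b"] = dqkv.sum(0)
        dy = dqkv @ params[f"b{b}_qkv_w"].T
        dpre, g[f"b{b}_ln1_g"], g[f"b{b}_ln1_b"] = _ln_bwd(dy, c["ln1c"])
        dtokens = dtokens + dpre

    g["cls"] = dtokens[0]
    dproj = dtokens[1:]
    g["proj_w"] = cache["x"].T @ dproj
    g["proj_b"] = dproj.sum(0)
    return g


def _bag_features(bag) -> np.ndarray:
    feats = getattr(bag, "features", bag)
    x = np.asarray(feats, dtype=np.float32)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("bag must be a non-empty (n_tiles, encoder_dim) matrix")
    return x


def forward(
    state: AggregatorState,
    bag,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> PredictionOutput:
    """Classify one bag. Evaluation mode is deterministic.

    ``bag`` may be a FeatureBag or a raw (n_tiles, encoder_dim) array. In
    training mode, tile dropout and attention dropout are applied and an
    ``rng`` is required; bags above the feature cap are subsampled.
    """
    cfg = state.config
    x = _bag_features(bag)
    if x.shape[1] != cfg.encoder_dim:
        raise ValueError(
            f"feature dim {x.shape[1]} does not match encoder_dim {cfg.encoder_dim}"
        )
    idx = _select_tiles(x, cfg, training, rng)
    logits, cache = _forward(state.params, x[idx], cfg, training, rng)
    attn = _attention_from_cache(cache, cfg)
    return PredictionOutput(
        logits=logits.astype(np.float64),
        probabilities=softmax(logits.astype(np.float64)),
        attention=attn,
        embedding=cache["embedding"].astype(np.float64),
    )


def _attention_from_cache(cache, config: ModelConfig) -> np.ndarray:
    # Head-averaged class-token attention of the final block, tiles only.
    a = cache["blocks"][-1]["attn"]  # (H, N, N), pre-dropout
    w = a[:, 0, 1:].mean(axis=0)
    s = w.sum()
    return (w / s).astype(np.float64) if s > 0 else w.astype(np.float64)


def extract_attention(state: AggregatorState, bag) -> np.ndarray:
    """Per-tile attention weights (>= 0, summing to 1), evaluation mode."""
    return forward(state, bag, training=False).attention


def embed_case(state: AggregatorState, bag) -> np.ndarray:
    """Pre-head class-token representation of a bag, evaluation mode."""
    return forward(state, bag, training=False).embedding


def loss_and_grads(
    state: AggregatorState,
    bag,
    label: int,
    rng: np.random.Generator | None = None,
    training: bool = True,
    class_weight: float = 1.0,
) -> tuple[float, dict]:
    """Weighted cross-entropy loss and parameter gradients for one case."""
    cfg = state.config
    x = _bag_features(bag)
    idx = _select_tiles(x, cfg, training, rng)
    logits, cache = _forward(state.params, x[idx], cfg, training, rng)
    logits64 = logits.astype(np.float64)
    probs = softmax(logits64)
    loss = -class_weight * np.log(max(probs[label], 1e-12))
    dlogits = (probs - np.eye(cfg.n_classes)[label]) * class_weight
    grads = _backward(dlogits.astype(np.float32), state.params, cache, cfg)
    return float(loss), grads


def case_loss(
    state: AggregatorState, bag, label: int, class_weight: float = 1.0
) -> float:
    """Evaluation-mode weighted cross-entropy of one case."""
    out = forward(state, bag, training=False)
    return float(-class_weight * np.log(max(out.probabilities[label], 1e-12)))


# ---------------------------------------------------------------------------
# Checkpointing: one .npz file with the config embedded as JSON.


def save_checkpoint(state: AggregatorState, path) -> None:
    meta = json.dumps({"config": state.config.__dict__, "seed": state.seed})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state.params)


def load_checkpoint(path) -> AggregatorState:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {k: data[k] for k in data.files if k != "__meta__"}
    return AggregatorState(
        params=params, config=ModelConfig(**meta["config"]), seed=meta["seed"]
    )
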