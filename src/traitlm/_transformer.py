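"""Tiny decoder-only transformer with manual reverse-mode gradients.

A minimal pre-norm causal transformer (token + learned positional
embeddings, multi-head attention with optional grouped key/value heads,
ReLU MLP) written against numpy, with a hand-derived backward pass and an
Adam optimizer.  Trait conditioning enters through an extra key/value slot
at attention position 0 (the "dummy" position): at every injected layer the
trait vector is linearly projected to a key state and a value state that
all real tokens may attend to.  The dummy slot has no query, receives no
loss, and never appears in the token stream.

All arrays are float64; parameters live in a flat ``{name: ndarray}`` dict
(adapter projections under ``adapter.{layer}.{k,v}``) so that optimizers
can update arbitrary subsets (e.g. adapter-only fine-tuning).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

LN_EPS = 1e-5
NEG_INF = -1e9


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of the base language model."""

    vocab_size: int
    num_layers: int = 2
    hidden_size: int = 64
    num_heads: int = 4
    num_kv_heads: int = 2
    head_dim: int = 16
    max_sequence_length: int = 64
    mlp_ratio: int = 4
    pad_id: int = 0
    sos_id: int = 1
    eos_id: int = 2
    unk_id: int = 3

    def __post_init__(self) -> None:
        if self.num_layers < 1:
            raise ValueError("need at least one layer")
        if self.hidden_size != self.num_heads * self.head_dim:
            raise ValueError("hidden_size must equal num_heads * head_dim")
        if self.num_heads % self.num_kv_heads != 0:
            raise ValueError("num_kv_heads must divide num_heads")
        if self.vocab_size <= max(self.pad_id, self.sos_id, self.eos_id, self.unk_id):
            raise ValueError("special token ids must lie inside the vocabulary")

    @property
    def kv_width(self) -> int:
        return self.num_kv_heads * self.head_dim

    def to_dict(self) -> dict:
        return {
            "vocab_size": self.vocab_size,
            "num_layers": self.num_layers,
            "hidden_size": self.hidden_size,
            "num_heads": self.num_heads,
            "num_kv_heads": self.num_kv_heads,
            "head_dim": self.head_dim,
            "max_sequence_length": self.max_sequence_length,
            "mlp_ratio": self.mlp_ratio,
            "pad_id": self.pad_id,
            "sos_id": self.sos_id,
            "eos_id": self.eos_id,
            "unk_id": self.unk_id,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        return cls(**{k: int(v) for k, v in d.items()})


def init_base_params(cfg: ModelConfig, rng: np.random.Generator, scale: float = 0.02) -> dict:
    """Gaussian-initialized base model parameters (no adapter)."""
    h, m = cfg.hidden_size, cfg.mlp_ratio * cfg.hidden_size
    p: dict[str, np.ndarray] = {
        "tok_emb": rng.normal(0.0, scale, (cfg.vocab_size, h)),
        "pos_emb": rng.normal(0.0, scale, (cfg.max_sequence_length, h)),
        "lnf_g": np.ones(h),
        "lnf_b": np.zeros(h),
        "out_w": rng.normal(0.0, scale, (h, cfg.vocab_size)),
        "out_b": np.zeros(cfg.vocab_size),
    }
    for l in range(cfg.num_layers):
        p[f"{l}.ln1_g"] = np.ones(h)
        p[f"{l}.ln1_b"] = np.zeros(h)
        p[f"{l}.wq"] = rng.normal(0.0, scale, (h, h))
        p[f"{l}.wk"] = rng.normal(0.0, scale, (h, cfg.kv_width))
        p[f"{l}.wv"] = rng.normal(0.0, scale, (h, cfg.kv_width))
        p[f"{l}.wo"] = rng.normal(0.0, scale, (h, h))
        p[f"{l}.ln2_g"] = np.ones(h)
        p[f"{l}.ln2_b"] = np.zeros(h)
        p[f"{l}.w1"] = rng.normal(0.0, scale, (h, m))
        p[f"{l}.b1"] = np.zeros(m)
        p[f"{l}.w2"] = rng.normal(0.0, scale, (m, h))
        p[f"{l}.b2"] = np.zeros(h)
    return p


def _layer_norm(x: np.ndarray, g: np.ndarray, b: np.ndarray):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + LN_EPS)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv)


def _layer_norm_bwd(dy: np.ndarray, g: np.ndarray, cache):
    xhat, inv = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward(
    params: Mapping[str, np.ndarray],
    cfg: ModelConfig,
    ids: np.ndarray,
    lengths: np.ndarray,
    profiles: np.ndarray | None,
    inject_layers: frozenset[int],
    include_bias: bool,
    need_cache: bool = False,
):
    """Run the model over a padded batch.

    ids : (B, T) int token ids, padded with pad_id
    lengths : (B,) valid lengths
    profiles : (B, t) trait vectors, or None when no layer is injected
    Returns (logits, cache); logits (B, T, V).  Real tokens occupy positions
    1..T (position 0 is reserved for the dummy trait slot).
    """
    B, T = ids.shape
    if T + 1 > cfg.max_sequence_length:
        raise ValueError(
            f"sequence length {T} exceeds max_sequence_length - 1 = "
            f"{cfg.max_sequence_length - 1}"
        )
    nh, nkv, hd = cfg.num_heads, cfg.num_kv_heads, cfg.head_dim
    g_rep = nh // nkv
    scale = 1.0 / np.sqrt(hd)

    if profiles is not None:
        ptil = np.asarray(profiles, float)
        if include_bias:
            ptil = np.concatenate([ptil, np.ones((B, 1))], axis=1)
    else:
        ptil = None

    x = params["tok_emb"][ids] + params["pos_emb"][1 : T + 1][None, :, :]

    pos = np.arange(T)
    key_ok = pos[None, None, :] <= pos[None, :, None]  # (1, T, T) causal
    key_ok = key_ok & (pos[None, None, :] < lengths[:, None, None])  # pad keys
    tok_bias = np.where(key_ok, 0.0, NEG_INF)  # (B, T, T)

    cache = {"ids": ids, "ptil": ptil, "x0": x} if need_cache else None
    layer_caches = []

    for l in range(cfg.num_layers):
        injected = l in inject_layers
        xn, ln1c = _layer_norm(x, params[f"{l}.ln1_g"], params[f"{l}.ln1_b"])
        q = (xn @ params[f"{l}.wq"]).reshape(B, T, nh, hd).transpose(0, 2, 1, 3)
        k = (xn @ params[f"{l}.wk"]).reshape(B, T, nkv, hd).transpose(0, 2, 1, 3)
        v = (xn @ params[f"{l}.wv"]).reshape(B, T, nkv, hd).transpose(0, 2, 1, 3)
        if injected:
            kd = (ptil @ params[f"adapter.{l}.k"]).reshape(B, nkv, 1, hd)
            vd = (ptil @ params[f"adapter.{l}.v"]).reshape(B, nkv, 1, hd)
            K = np.concatenate([kd, k], axis=2)
            V = np.concatenate([vd, v], axis=2)
            bias = np.concatenate([np.zeros((B, T, 1)), tok_bias], axis=2)
        else:
            K, V, bias = k, v, tok_bias
        Kr = np.repeat(K, g_rep, axis=1)
        Vr = np.repeat(V, g_rep, axis=1)
        scores = np.einsum("bhqd,bhkd->bhqk", q, Kr) * scale + bias[:, None, :, :]
        A = _softmax(scores)
        ctx = np.einsum("bhqk,bhkd->bhqd", A, Vr)
        ctx2 = ctx.transpose(0, 2, 1, 3).reshape(B, T, nh * hd)
        attn_out = ctx2 @ params[f"{l}.wo"]
        x_attn = x + attn_out

        xn2, ln2c = _layer_norm(x_attn, params[f"{l}.ln2_g"], params[f"{l}.ln2_b"])
        pre = xn2 @ params[f"{l}.w1"] + params[f"{l}.b1"]
        act = np.maximum(pre, 0.0)
        mlp = act @ params[f"{l}.w2"] + params[f"{l}.b2"]
        x_new = x_attn + mlp

        if need_cache:
            layer_caches.append(
                dict(
                    injected=injected, x=x, xn=xn, ln1c=ln1c, q=q, A=A, Vr=Vr,
                    Kr=Kr, ctx2=ctx2, x_attn=x_attn, xn2=xn2, ln2c=ln2c,
                    pre=pre, act=act,
                )
            )
        x = x_new

    xf, lnfc = _layer_norm(x, params["lnf_g"], params["lnf_b"])
    logits = xf @ params["out_w"] + params["out_b"]
    if need_cache:
        cache["layers"] = layer_caches
        cache["x_last"] = x
        cache["xf"] = xf
        cache["lnfc"] = lnfc
    return logits, cache


def loss_and_grads(
    params: Mapping[str, np.ndarray],
    cfg: ModelConfig,
    ids: np.ndarray,
    lengths: np.ndarray,
    targets: np.ndarray,
    target_mask: np.ndarray,
    profiles: np.ndarray | None,
    inject_layers: frozenset[int],
    include_bias: bool,
):
    """Mean next-token cross-entropy over unmasked targets, with gradients
    for every parameter present in ``params`` (adapter entries included)."""
    B, T = ids.shape
    nh, nkv, hd = cfg.num_heads, cfg.num_kv_heads, cfg.head_dim
    g_rep = nh // nkv
    scale = 1.0 / np.sqrt(hd)

    logits, cache = forward(
        params, cfg, ids, lengths, profiles, inject_layers, include_bias,
        need_cache=True,
    )
    probs = _softmax(logits)
    n_valid = int(target_mask.sum())
    if n_valid == 0:
        raise ValueError("no unmasked targets")
    b_idx, t_idx = np.nonzero(target_mask)
    logp = np.log(probs[b_idx, t_idx, targets[b_idx, t_idx]] + 1e-300)
    loss = -logp.sum() / n_valid

    grads: dict[str, np.ndarray] = {}
    dlogits = probs.copy()
    dlogits[b_idx, t_idx, targets[b_idx, t_idx]] -= 1.0
    dlogits *= target_mask[:, :, None] / n_valid

    xf = cache["xf"]
    grads["out_w"] = xf.reshape(-1, cfg.hidden_size).T @ dlogits.reshape(-1, cfg.vocab_size)
    grads["out_b"] = dlogits.sum(axis=(0, 1))
    dxf = dlogits @ params["out_w"].T
    dx, grads["lnf_g"], grads["lnf_b"] = _layer_norm_bwd(dxf, params["lnf_g"], cache["lnfc"])

    ptil = cache["ptil"]
    for l in range(cfg.num_layers - 1, -1, -1):
        c = cache["layers"][l]
        # MLP
        dmlp = dx
        grads[f"{l}.w2"] = c["act"].reshape(-1, c["act"].shape[-1]).T @ dmlp.reshape(
            -1, cfg.hidden_size
        )
        grads[f"{l}.b2"] = dmlp.sum(axis=(0, 1))
        dact = dmlp @ params[f"{l}.w2"].T
        dpre = dact * (c["pre"] > 0)
        grads[f"{l}.w1"] = c["xn2"].reshape(-1, cfg.hidden_size).T @ dpre.reshape(
            -1, dpre.shape[-1]
        )
        grads[f"{l}.b1"] = dpre.sum(axis=(0, 1))
        dxn2 = dpre @ params[f"{l}.w1"].T
        dx_ln2, grads[f"{l}.ln2_g"], grads[f"{l}.ln2_b"] = _layer_norm_bwd(
            dxn2, params[f"{l}.ln2_g"], c["ln2c"]
        )
        dx_attn = dx + dx_ln2

        # attention output
        dattn_out = dx_attn
        grads[f"{l}.wo"] = c["ctx2"].reshape(-1, cfg.hidden_size).T @ dattn_out.reshape(
            -1, cfg.hidden_size
        )
        dctx2 = dattn_out @ params[f"{l}.wo"].T
        dctx = dctx2.reshape(B, T, nh, hd).transpose(0, 2, 1, 3)
        A, Vr, Kr, q = c["A"], c["Vr"], c["Kr"], c["q"]
        dA = np.einsum("bhqd,bhkd->bhqk", dctx, Vr)
        dVr = np.einsum("bhqk,bhqd->bhkd", A, dctx)
        ds = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dq = np.einsum("bhqk,bhkd->bhqd", ds, Kr) * scale
        dKr = np.einsum("bhqk,bhqd->bhkd", ds, q) * scale
        # un-repeat grouped kv heads
        S = dKr.shape[2]
        dK = dKr.reshape(B, nkv, g_rep, S, hd).sum(axis=2)
        dV = dVr.reshape(B, nkv, g_rep, S, hd).sum(axis=2)
        if c["injected"]:
            dkd, dk = dK[:, :, :1, :], dK[:, :, 1:, :]
            dvd, dv = dV[:, :, :1, :], dV[:, :, 1:, :]
            grads[f"adapter.{l}.k"] = ptil.T @ dkd.reshape(B, -1)
            grads[f"adapter.{l}.v"] = ptil.T @ dvd.reshape(B, -1)
        else:
            dk, dv = dK, dV
        dq2 = dq.transpose(0, 2, 1, 3).reshape(B, T, nh * hd)
        dk2 = dk.transpose(0, 2, 1, 3).reshape(B, T, nkv * hd)
        dv2 = dv.transpose(0, 2, 1, 3).reshape(B, T, nkv * hd)
        xn = c["xn"]
        xn_flat = xn.reshape(-1, cfg.hidden_size)
        grads[f"{l}.wq"] = xn_flat.T @ dq2.reshape(-1, nh * hd)
        grads[f"{l}.wk"] = xn_flat.T @ dk2.reshape(-1, nkv * hd)
        grads[f"{l}.wv"] = xn_flat.T @ dv2.reshape(-1, nkv * hd)
        dxn = (
            dq2 @ params[f"{l}.wq"].T
            + dk2 @ params[f"{l}.wk"].T
            + dv2 @ params[f"{l}.wv"].T
        )
        dx_ln1, grads[f"{l}.ln1_g"], grads[f"{l}.ln1_b"] = _layer_norm_bwd(
            dxn, params[f"{l}.ln1_g"], c["ln1c"]
        )
        dx = dx_attn + dx_ln1

    grads["tok_emb"] = np.zeros_like(params["tok_emb"])
    np.add.at(grads["tok_emb"], cache["ids"], dx)
    grads["pos_emb"] = np.zeros_like(params["pos_emb"])
    grads["pos_emb"][1 : T + 1] = dx.sum(axis=0)
    return loss, grads


class Adam:
    """Plain Adam with bias correction, updating a chosen key subset."""

    def __init__(self, params: dict, lr: float = 5e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 trainable: set[str] | None = None):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.trainable = set(params) if trainable is None else set(trainable)
        self.m = {k: np.zeros_like(params[k]) for k in self.trainable}
        self.v = {k: np.zeros_like(params[k]) for k in self.trainable}
        self.step_count = 0

    def step(self, params: dict, grads: Mapping[str, np.ndarray]) -> None:
        self.step_count += 1
        bc1 = 1.0 - self.b1 ** self.step_count
        bc2 = 1.0 - self.b2 ** self.step_count
        for k in self.trainable:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] = params[k] - self.lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + self.eps
            )
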