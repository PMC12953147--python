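"""Trait-conditioned autoregressive language model.

The conditioning mechanism: a trait-score vector ``p`` (standardized units,
optionally bias-augmented to ``p~ = [p, 1]``) is mapped at every injected
transformer layer ``l`` through two learned projection matrices into that
layer's key/value width,

    key_l  = p~ @ Wk_l        value_l = p~ @ Wv_l ,

and supplied as the key/value states of a dummy position 0 that every real
token may attend to.  The model is trained on the text-reconstruction
objective: maximize prod_j P(w_j | w_1..w_{j-1}, p) over messages labeled
with (estimated) trait scores.  The added parameter count is

    2 * n_injected_layers * (t + 1) * num_kv_heads * head_dim

with the bias convention, e.g. 55,296 for an 18-layer model with key/value
width 256 and five trait dimensions.

Everything here runs on the pure-numpy transformer in ``_transformer``;
the adapter applies unchanged to any decoder-only architecture with
per-layer key/value states.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._transformer import Adam, ModelConfig, forward, init_base_params, loss_and_grads
from .corpus_io import CorpusRecord
from .score_estimation import Standardization
from .trait_space import TraitProfile, TraitSpec

logger = logging.getLogger("traitlm")

SPECIAL_TOKENS = ("[PAD]", "[SOS]", "[EOS]", "[UNK]")

CHECKPOINT_FORMAT_VERSION = 1


class Vocabulary:
    """Token <-> id mapping with the four special tokens at ids 0..3."""

    def __init__(self, words: Sequence[str]):
        self.tokens: tuple[str, ...] = SPECIAL_TOKENS + tuple(words)
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        self._index = {w: i for i, w in enumerate(self.tokens)}

    @classmethod
    def from_corpus(cls, token_seqs: Iterable[Sequence[str]]) -> "Vocabulary":
        words = sorted({w for seq in token_seqs for w in seq} - set(SPECIAL_TOKENS))
        return cls(words)

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def sos_id(self) -> int:
        return 1

    @property
    def eos_id(self) -> int:
        return 2

    @property
    def unk_id(self) -> int:
        return 3

    def encode(self, words: Sequence[str]) -> tuple[int, ...]:
        return tuple(self._index.get(w, self.unk_id) for w in words)

    def decode(self, ids: Sequence[int]) -> tuple[str, ...]:
        return tuple(self.tokens[i] for i in ids)


@dataclass(frozen=True)
class AdapterConfig:
    """Shape of the trait adapter.

    ``latent_size`` is the trait dimension t; with ``include_bias`` the
    effective projection input width is t + 1 (the constant-1 component lets
    the dummy states carry a profile-independent intercept).
    ``inject_layers`` is None for all layers, or an explicit layer set.
    """

    latent_size: int
    include_bias: bool = True
    inject_layers: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.latent_size < 0:
            raise ValueError("latent_size must be >= 0")

    @property
    def input_width(self) -> int:
        return self.latent_size + (1 if self.include_bias else 0)

    def layers(self, model_cfg: ModelConfig) -> frozenset[int]:
        if self.inject_layers is None:
            return frozenset(range(model_cfg.num_layers))
        bad = [l for l in self.inject_layers if not 0 <= l < model_cfg.num_layers]
        if bad:
            raise ValueError(f"inject_layers out of range: {bad}")
        return frozenset(self.inject_layers)

    def to_dict(self) -> dict:
        return {
            "latent_size": self.latent_size,
            "include_bias": self.include_bias,
            "inject_layers": list(self.inject_layers)
            if self.inject_layers is not None
            else None,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AdapterConfig":
        return cls(
            int(d["latent_size"]),
            bool(d["include_bias"]),
            tuple(d["inject_layers"]) if d.get("inject_layers") is not None else None,
        )


def count_adapter_params(model_cfg: ModelConfig, adapter_cfg: AdapterConfig) -> int:
    """Parameters the adapter adds: key and value projections at every
    injected layer, each of shape (t + bias) x (num_kv_heads * head_dim)."""
    n_layers = len(adapter_cfg.layers(model_cfg))
    return 2 * n_layers * adapter_cfg.input_width * model_cfg.kv_width


@dataclass
class AdapterProjectionSet:
    """The learned per-layer key/value trait projections."""

    model_cfg: ModelConfig
    adapter_cfg: AdapterConfig
    matrices: dict[int, dict[str, np.ndarray]]  # layer -> {"k": Wk, "v": Wv}

    def __post_init__(self) -> None:
        expect = (self.adapter_cfg.input_width, self.model_cfg.kv_width)
        for l, kv in self.matrices.items():
            for name in ("k", "v"):
                if kv[name].shape != expect:
                    raise ValueError(
                        f"layer {l} {name}-projection has shape {kv[name].shape}, "
                        f"expected {expect}"
                    )
                if not np.all(np.isfinite(kv[name])):
                    raise ValueError(f"non-finite entries in layer {l} projections")

    def as_params(self) -> dict[str, np.ndarray]:
        out = {}
        for l, kv in self.matrices.items():
            out[f"adapter.{l}.k"] = kv["k"]
            out[f"adapter.{l}.v"] = kv["v"]
        return out

    @classmethod
    def from_params(
        cls, params: Mapping[str, np.ndarray], model_cfg: ModelConfig,
        adapter_cfg: AdapterConfig,
    ) -> "AdapterProjectionSet":
        mats = {
            l: {"k": params[f"adapter.{l}.k"], "v": params[f"adapter.{l}.v"]}
            for l in sorted(adapter_cfg.layers(model_cfg))
        }
        return cls(model_cfg, adapter_cfg, mats)


def make_projection_set(
    model_cfg: ModelConfig,
    adapter_cfg: AdapterConfig,
    init_scale: float = 0.02,
    seed: int = 0,
) -> AdapterProjectionSet:
    """Gaussian-initialized projections, deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    shape = (adapter_cfg.input_width, model_cfg.kv_width)
    mats = {
        l: {
            "k": rng.normal(0.0, 1.0, shape) * init_scale,
            "v": rng.normal(0.0, 1.0, shape) * init_scale,
        }
        for l in sorted(adapter_cfg.layers(model_cfg))
    }
    return AdapterProjectionSet(model_cfg, adapter_cfg, mats)


def _profile_array(profile, t: int) -> np.ndarray:
    scores = profile.scores if isinstance(profile, TraitProfile) else np.asarray(profile, float)
    scores = scores.reshape(-1)
    if scores.shape[0] != t:
        raise ValueError(f"profile length {scores.shape[0]} != latent_size {t}")
    return scores


def inject_trait_state(
    profile, projections: AdapterProjectionSet, layer_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """The dummy position's key and value states at one layer:
    ``p~ @ Wk_l`` and ``p~ @ Wv_l``."""
    if layer_index not in projections.matrices:
        raise ValueError(f"layer {layer_index} is not an injected layer")
    p = _profile_array(profile, projections.adapter_cfg.latent_size)
    if projections.adapter_cfg.include_bias:
        p = np.concatenate([p, [1.0]])
    kv = projections.matrices[layer_index]
    return p @ kv["k"], p @ kv["v"]


@dataclass(frozen=True)
class ScoredMessage:
    """A tokenized message (integer ids, specials excluded) with the trait
    profile it was written under."""

    tokens: tuple[int, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.tokens) < 1:
            raise ValueError("message must contain at least one token")
        arr = np.asarray(self.scores, float).reshape(-1)
        arr.flags.writeable = False
        object.__setattr__(self, "scores", arr)
        object.__setattr__(self, "tokens", tuple(int(t) for t in self.tokens))

    @property
    def n(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class GenerationRequest:
    """One sampling request: trait profile, optional prompt, policy, seed."""

    profile: object  # TraitProfile or array-like
    prompt_tokens: tuple[int, ...] = ()
    max_new_tokens: int = 16
    policy: str = "topk"  # greedy | temperature | topk | nucleus
    temperature: float = 1.0
    top_k: int = 40
    top_p: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_new_tokens < 0:
            raise ValueError("max_new_tokens must be >= 0")
        if self.policy not in ("greedy", "temperature", "topk", "nucleus"):
            raise ValueError(f"unknown sampling policy {self.policy!r}")
        if self.policy != "greedy" and self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 5e-4
    seed: int = 0
    freeze_base: bool = False
    init_scale: float = 0.02


@dataclass
class Checkpoint:
    """A trained model: base weights + adapter projections + tokenizer +
    the score-standardization constants the training labels used."""

    model_cfg: ModelConfig
    adapter_cfg: AdapterConfig
    params: dict[str, np.ndarray]
    vocab: Vocabulary
    trait_names: tuple[str, ...] = ()
    standardization: Standardization | None = None
    history: list[float] = field(default_factory=list)

    @property
    def projections(self) -> AdapterProjectionSet:
        return AdapterProjectionSet.from_params(
            self.params, self.model_cfg, self.adapter_cfg
        )

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "model_config": self.model_cfg.to_dict(),
            "adapter_config": self.adapter_cfg.to_dict(),
            "vocab_words": list(self.vocab.tokens[len(SPECIAL_TOKENS):]),
            "trait_names": list(self.trait_names),
            "standardization": self.standardization.to_dict()
            if self.standardization
            else None,
            "history": self.history,
        }
        (d / "manifest.json").write_text(json.dumps(manifest), encoding="utf-8")
        np.savez(d / "weights.npz", **self.params)

    @classmethod
    def load(cls, directory: str | Path) -> "Checkpoint":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text(encoding="utf-8"))
        if manifest.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError("unsupported checkpoint format version")
        with np.load(d / "weights.npz") as npz:
            params = {k: npz[k] for k in npz.files}
        return cls(
            model_cfg=ModelConfig.from_dict(manifest["model_config"]),
            adapter_cfg=AdapterConfig.from_dict(manifest["adapter_config"]),
            params=params,
            vocab=Vocabulary(manifest["vocab_words"]),
            trait_names=tuple(manifest.get("trait_names") or ()),
            standardization=Standardization.from_dict(manifest["standardization"])
            if manifest.get("standardization")
            else None,
            history=list(manifest.get("history") or []),
        )


def _batchify(
    messages: Sequence[ScoredMessage], cfg: ModelConfig, t: int
):
    """Pad a batch into (ids, lengths, targets, target_mask, profiles).

    Each message is evaluated as [SOS] w_1..w_n with targets w_1..w_n [EOS]
    (n+1 predictions); the dummy trait slot is position 0 and is handled
    inside the attention, not in the token stream.
    """
    specials = {cfg.pad_id, cfg.sos_id, cfg.eos_id}
    for m in messages:
        if any(tok in specials for tok in m.tokens):
            raise ValueError("special tokens are not allowed inside a message body")
        if any(not 0 <= tok < cfg.vocab_size for tok in m.tokens):
            raise ValueError("token id outside vocabulary")
        if m.n + 2 > cfg.max_sequence_length:
            raise ValueError(
                f"message length {m.n} exceeds max_sequence_length - 2 = "
                f"{cfg.max_sequence_length - 2}"
            )
    B = len(messages)
    T = max(m.n for m in messages) + 1  # [SOS] + body
    ids = np.full((B, T), cfg.pad_id, dtype=np.int64)
    targets = np.full((B, T), cfg.pad_id, dtype=np.int64)
    mask = np.zeros((B, T), dtype=bool)
    profiles = np.zeros((B, t))
    lengths = np.zeros(B, dtype=np.int64)
    for i, m in enumerate(messages):
        n = m.n
        ids[i, 0] = cfg.sos_id
        ids[i, 1 : n + 1] = m.tokens
        targets[i, :n] = m.tokens
        targets[i, n] = cfg.eos_id
        mask[i, : n + 1] = True
        lengths[i] = n + 1
        if t:
            profiles[i] = _profile_array(m.scores, t)
    return ids, lengths, targets, mask, profiles


def conditional_log_likelihood(
    checkpoint: Checkpoint, message: ScoredMessage
) -> tuple[np.ndarray, float]:
    """Per-token log-probabilities and total negative log-likelihood of a
    message under its trait profile (n+1 terms: the body and [EOS])."""
    cfg, acfg = checkpoint.model_cfg, checkpoint.adapter_cfg
    ids, lengths, targets, mask, profiles = _batchify([message], cfg, acfg.latent_size)
    logits, _ = forward(
        checkpoint.params, cfg, ids, lengths, profiles, acfg.layers(cfg),
        acfg.include_bias,
    )
    z = logits[0] - logits[0].max(axis=-1, keepdims=True)
    logp_all = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    n = message.n
    logp = logp_all[np.arange(n + 1), targets[0, : n + 1]]
    return logp, float(-logp.sum())


def corpus_mean_nll(checkpoint: Checkpoint, messages: Sequence[ScoredMessage],
                    batch_size: int = 64) -> float:
    """Mean per-token NLL over a corpus (body + [EOS] tokens)."""
    total, count = 0.0, 0
    order = sorted(range(len(messages)), key=lambda i: messages[i].n)
    for start in range(0, len(order), batch_size):
        batch = [messages[i] for i in order[start : start + batch_size]]
        cfg, acfg = checkpoint.model_cfg, checkpoint.adapter_cfg
        ids, lengths, targets, mask, profiles = _batchify(
            batch, cfg, acfg.latent_size
        )
        logits, _ = forward(
            checkpoint.params, cfg, ids, lengths, profiles, acfg.layers(cfg),
            acfg.include_bias,
        )
        z = logits - logits.max(axis=-1, keepdims=True)
        logp_all = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
        b_idx, t_idx = np.nonzero(mask)
        total -= logp_all[b_idx, t_idx, targets[b_idx, t_idx]].sum()
        count += len(b_idx)
    return total / count


def train_adapter(
    corpus: Sequence[ScoredMessage],
    model_cfg: ModelConfig,
    adapter_cfg: AdapterConfig,
    train_cfg: TrainConfig,
    vocab: Vocabulary,
    base_params: Mapping[str, np.ndarray] | None = None,
    trait_names: Sequence[str] = (),
    standardization: Standardization | None = None,
) -> Checkpoint:
    """Train on the text-reconstruction objective (next-token cross-entropy
    conditioned on each message's trait profile).

    With ``freeze_base`` only the adapter projections are updated (the use
    case of attaching an adapter to a fixed pretrained model); otherwise the
    whole tiny model is trained jointly.  Deterministic for a fixed seed.
    """
    if len(corpus) == 0:
        raise ValueError("training corpus is empty")
    rng = np.random.default_rng(train_cfg.seed)
    params = (
        {k: v.copy() for k, v in base_params.items()}
        if base_params is not None
        else init_base_params(model_cfg, rng, train_cfg.init_scale)
    )
    proj = make_projection_set(
        model_cfg, adapter_cfg, train_cfg.init_scale,
        seed=int(rng.integers(2**31)),
    )
    params.update(proj.as_params())
    inject = adapter_cfg.layers(model_cfg)

    trainable = (
        {k for k in params if k.startswith("adapter.")}
        if train_cfg.freeze_base
        else set(params)
    )
    opt = Adam(params, lr=train_cfg.learning_rate, trainable=trainable)
    history: list[float] = []
    n = len(corpus)
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, train_cfg.batch_size):
            batch = [corpus[i] for i in order[start : start + train_cfg.batch_size]]
            ids, lengths, targets, mask, profiles = _batchify(
                batch, model_cfg, adapter_cfg.latent_size
            )
            loss, grads = loss_and_grads(
                params, model_cfg, ids, lengths, targets, mask, profiles,
                inject, adapter_cfg.include_bias,
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches} "
                    f"(loss={loss}); lower the learning rate"
                )
            opt.step(params, grads)
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / n_batches)
        logger.info("epoch %d/%d: mean loss %.4f", epoch + 1, train_cfg.epochs,
                    history[-1])
    return Checkpoint(
        model_cfg=model_cfg,
        adapter_cfg=adapter_cfg,
        params=params,
        vocab=vocab,
        trait_names=tuple(trait_names),
        standardization=standardization,
        history=history,
    )


def _sample_from_logits(logits: np.ndarray, request: GenerationRequest,
                        rng: np.random.Generator) -> int:
    if request.policy == "greedy":
        return int(np.argmax(logits))
    z = logits / request.temperature
    if request.policy == "topk":
        k = min(request.top_k, z.shape[0])
        cutoff = np.partition(z, -k)[-k]
        z = np.where(z >= cutoff, z, -np.inf)
    elif request.policy == "nucleus":
        order = np.argsort(z)[::-1]
        p = np.exp(z[order] - z[order][0])
        p /= p.sum()
        keep = np.cumsum(p) - p < request.top_p
        keep[0] = True
        drop = np.ones_like(z, dtype=bool)
        drop[order[keep]] = False
        z = np.where(drop, -np.inf, z)
    z = z - z.max()
    p = np.exp(z)
    p /= p.sum()
    return int(rng.choice(p.shape[0], p=p))


def generate(checkpoint: Checkpoint, request: GenerationRequest) -> tuple[int, ...]:
    """Autoregressively sample a continuation conditioned on the trait
    profile.  Returns prompt + continuation token ids (no specials); stops
    at [EOS] or ``max_new_tokens``.  Deterministic for a fixed request."""
    cfg, acfg = checkpoint.model_cfg, checkpoint.adapter_cfg
    for tok in request.prompt_tokens:
        if not 0 <= tok < cfg.vocab_size:
            raise ValueError(f"prompt token id {tok} outside vocabulary")
    rng = np.random.default_rng(request.seed)
    profile = _profile_array(request.profile, acfg.latent_size)[None, :]
    body = list(request.prompt_tokens)
    inject = acfg.layers(cfg)
    for _ in range(request.max_new_tokens):
        ids = np.asarray([[cfg.sos_id] + body], dtype=np.int64)
        if ids.shape[1] + 1 >= cfg.max_sequence_length:
            break
        lengths = np.asarray([ids.shape[1]])
        logits, _ = forward(
            checkpoint.params, cfg, ids, lengths, profile, inject,
            acfg.include_bias,
        )
        step_logits = logits[0, -1].copy()
        step_logits[cfg.pad_id] = -np.inf
        step_logits[cfg.sos_id] = -np.inf
        tok = _sample_from_logits(step_logits, request, rng)
        if tok == cfg.eos_id:
            break
        body.append(tok)
    return tuple(body)


def records_to_messages(
    records: Sequence[CorpusRecord], vocab: Vocabulary, use: str = "scores_std"
) -> list[ScoredMessage]:
    """Convert scored corpus records into training messages (standardized
    scores by default)."""
    out = []
    for rec in records:
        scores = getattr(rec, use)
        if scores is None:
            raise ValueError(f"record {rec.message_id} has no {use}")
        if rec.tokens is None:
            raise ValueError(f"record {rec.message_id} is not tokenized")
        out.append(ScoredMessage(vocab.encode(rec.tokens), np.asarray(scores)))
    return out
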