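"""Synthetic trait-conditioned corpora with known ground truth.

Each simulated participant has a latent trait vector psi drawn i.i.d.
standard normal per dimension (so scores are already in standardized
units).  Messages are bags of word-like tokens drawn i.i.d. from a
log-linear vocabulary distribution,

    P(w | psi)  =  softmax( b_w + sum_i psi_i * beta_{i,w} ) ,

where each trait dimension i owns a set of designated "high" marker tokens
(beta_{i,w} = +beta), "low" marker tokens (beta_{i,w} = -beta), and the
remaining filler tokens are uncoupled.  The base logits b_w decay linearly
across the vocabulary, giving a mildly skewed background frequency profile.
The log-linear form makes expected marker frequencies computable in closed
form, so estimator recovery and rater behaviour can be checked against
exact oracles.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import CorpusRecord, write_corpus
from .score_estimation import ParticipantRecord

DEFAULT_TRAIT_NAMES = (
    "openness",
    "conscientiousness",
    "extraversion",
    "agreeableness",
    "neuroticism",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the simulated corpus.

    Defaults mirror short social-media messages labeled with standardized
    trait scores: five trait dimensions, a 60-word vocabulary with four
    high and four low marker words per dimension, a marker log-odds slope
    of 1 per SD, messages of 12-24 words (the length range of short social
    media posts and truncated blog openings), and 200 authors with 10
    messages each.
    """

    t: int = 5
    vocab: int = 60
    markers_per_trait: int = 4
    beta: float = 1.0
    message_length_range: tuple[int, int] = (12, 24)
    n_participants: int = 200
    messages_per_participant: int = 10
    heldout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError("need at least one trait dimension")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.vocab < 2 * self.t * self.markers_per_trait + 10:
            raise ValueError(
                "vocabulary too small: need >= 2*t*markers_per_trait + 10 words"
            )
        lo, hi = self.message_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid message_length_range")
        if not 0.0 <= self.heldout_fraction < 1.0:
            raise ValueError("heldout_fraction must lie in [0, 1)")

    @property
    def trait_names(self) -> tuple[str, ...]:
        if self.t <= len(DEFAULT_TRAIT_NAMES):
            return DEFAULT_TRAIT_NAMES[: self.t]
        return tuple(f"trait{i}" for i in range(self.t))


def vocabulary(config: SyntheticConfig) -> tuple[str, ...]:
    """The word list: trait markers first (``hi{i}_{j}``/``lo{i}_{j}``),
    then filler words (``w{j}``)."""
    words: list[str] = []
    for i in range(config.t):
        words.extend(f"hi{i}_{j}" for j in range(config.markers_per_trait))
        words.extend(f"lo{i}_{j}" for j in range(config.markers_per_trait))
    n_filler = config.vocab - len(words)
    words.extend(f"w{j}" for j in range(n_filler))
    return tuple(words)


def marker_table(config: SyntheticConfig) -> dict[int, dict[str, tuple[str, ...]]]:
    """Per trait dimension, the high- and low-pole marker words."""
    return {
        i: {
            "high": tuple(f"hi{i}_{j}" for j in range(config.markers_per_trait)),
            "low": tuple(f"lo{i}_{j}" for j in range(config.markers_per_trait)),
        }
        for i in range(config.t)
    }


def _coupling(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """(base logits b of length V, coupling matrix beta of shape (t, V))."""
    words = vocabulary(config)
    V = len(words)
    # markers share a common base rate so signal strength is identical
    # across trait dimensions; filler words carry a mildly skewed background
    n_markers = 2 * config.t * config.markers_per_trait
    b = np.zeros(V)
    b[n_markers:] = np.linspace(1.0, -1.0, V - n_markers)
    B = np.zeros((config.t, V))
    for i in range(config.t):
        off = 2 * i * config.markers_per_trait
        B[i, off : off + config.markers_per_trait] = config.beta
        B[i, off + config.markers_per_trait : off + 2 * config.markers_per_trait] = (
            -config.beta
        )
    return b, B


def token_distribution(profile: Sequence[float], config: SyntheticConfig) -> np.ndarray:
    """Exact P(w | psi) over the vocabulary — the closed-form oracle."""
    psi = np.asarray(profile, float).reshape(-1)
    if psi.shape[0] != config.t:
        raise ValueError(f"profile length {psi.shape[0]} != t={config.t}")
    b, B = _coupling(config)
    logits = b + psi @ B
    z = logits - logits.max()
    p = np.exp(z)
    return p / p.sum()


def sample_message(
    profile: Sequence[float], config: SyntheticConfig, rng: np.random.Generator
) -> tuple[str, ...]:
    """One message: i.i.d. tokens from the log-linear distribution, length
    uniform in ``message_length_range``."""
    words = vocabulary(config)
    p = token_distribution(profile, config)
    lo, hi = config.message_length_range
    length = int(rng.integers(lo, hi + 1))
    idx = rng.choice(len(words), size=length, p=p)
    return tuple(words[i] for i in idx)


def sample_participants(config: SyntheticConfig) -> list[ParticipantRecord]:
    """Simulate the full author panel, deterministic for the config seed."""
    rng = np.random.default_rng(config.seed)
    psi = rng.standard_normal((config.n_participants, config.t))
    out = []
    for pi in range(config.n_participants):
        messages = tuple(
            sample_message(psi[pi], config, rng)
            for _ in range(config.messages_per_participant)
        )
        out.append(
            ParticipantRecord(
                participant_id=f"p{pi:04d}",
                messages=messages,
                trait_scores=tuple(psi[pi]),
            )
        )
    return out


def participants_to_records(
    participants: Sequence[ParticipantRecord],
) -> list[CorpusRecord]:
    """Flatten the panel into per-message corpus records carrying the true
    author-level scores (message-level truth equals the author's psi)."""
    records = []
    for p in participants:
        for mi, msg in enumerate(p.messages):
            records.append(
                CorpusRecord(
                    message_id=f"{p.participant_id}_m{mi:03d}",
                    participant_id=p.participant_id,
                    text=" ".join(msg),
                    tokens=msg,
                    scores_raw=p.trait_scores,
                    scores_std=p.trait_scores,
                )
            )
    return records


def train_heldout_split(
    records: Sequence[CorpusRecord], config: SyntheticConfig
) -> tuple[list[CorpusRecord], list[CorpusRecord]]:
    """Deterministic message-level split; every participant keeps messages
    in both partitions when the held-out fraction allows."""
    rng = np.random.default_rng(config.seed + 1)
    by_participant: dict[str, list[CorpusRecord]] = {}
    for rec in records:
        by_participant.setdefault(rec.participant_id or "", []).append(rec)
    train, heldout = [], []
    for pid in sorted(by_participant):
        recs = by_participant[pid]
        n_hold = int(round(config.heldout_fraction * len(recs)))
        held_idx = set(rng.choice(len(recs), size=n_hold, replace=False).tolist())
        for i, rec in enumerate(recs):
            (heldout if i in held_idx else train).append(rec)
    return train, heldout


def make_fixture(
    config: SyntheticConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write train/held-out JSONL corpora and the participant truth table.

    Returns the paths: ``{"train": ..., "heldout": ..., "truth": ...}``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    participants = sample_participants(config)
    records = participants_to_records(participants)
    train, heldout = train_heldout_split(records, config)
    paths = {
        "train": out_dir / "train.jsonl",
        "heldout": out_dir / "heldout.jsonl",
        "truth": out_dir / "truth.csv",
    }
    write_corpus(paths["train"], train)
    write_corpus(paths["heldout"], heldout)
    with paths["truth"].open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", *config.trait_names])
        for p in participants:
            writer.writerow([p.participant_id, *[format(s, ".10g") for s in p.trait_scores]])
    return paths
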