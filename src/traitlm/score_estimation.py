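"""Message-level trait score estimation.

Trait scores (personality, depression, age, ...) are usually measured per
*participant*, not per message.  The pipeline here fits a linear model from a
participant's pooled word-frequency features to their trait scores,

    W_i = argmin_W  sum_p || psi_{p,i} - W . X_p ||^2  (+ ridge penalty),

one row per trait dimension, and then *transfers* the fitted matrices to
single messages: each message m receives the estimated raw score vector
(W_1 . X_m, ..., W_t . X_m).  Standardizing those estimates over the training
corpus yields the per-message conditioning scores used to train the
generative adapter; the standardization constants are frozen so that
generation-time inputs like (0, 0, +3, 0, 0) refer to the same scale.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.linear_model import Ridge

from .corpus_io import CorpusRecord
from .trait_space import TraitSpec

logger = logging.getLogger("traitlm")

DEFAULT_RIDGE_LAMBDA = 1e-3


class SingularFitWarning(UserWarning):
    """The design matrix was rank-deficient with lambda=0; the minimum-norm
    solution was returned."""


@dataclass(frozen=True)
class FeatureVector:
    """Non-negative features over a fixed vocabulary (relative word
    frequencies or topic loadings); ``empty`` marks an all-out-of-vocabulary
    message for which the estimator is undefined."""

    values: np.ndarray
    empty: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float).reshape(-1)
        if not np.all(np.isfinite(arr)):
            raise ValueError("features must be finite")
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    @property
    def d(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ParticipantRecord:
    """A participant's messages and their measured raw trait scores."""

    participant_id: str
    messages: tuple[tuple[str, ...], ...]
    trait_scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.messages) == 0:
            raise ValueError("participant needs at least one message")
        if not all(np.isfinite(self.trait_scores)):
            raise ValueError("trait scores must be finite")


@dataclass
class Standardization:
    """Frozen per-dimension mean/SD of estimated raw scores on the training
    corpus."""

    mean: np.ndarray
    sd: np.ndarray

    def apply(self, raw: np.ndarray) -> np.ndarray:
        return (np.asarray(raw) - self.mean) / self.sd

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Standardization":
        return cls(np.asarray(d["mean"], float), np.asarray(d["sd"], float))


@dataclass
class LinearTraitEstimator:
    """The fitted trait matrices W (shape t x d) over a feature vocabulary."""

    W: np.ndarray
    feature_vocabulary: tuple[str, ...]
    lam: float = DEFAULT_RIDGE_LAMBDA
    trait_names: tuple[str, ...] = ()
    mode: str = "relative_frequency"
    standardization: Standardization | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[1] != len(self.feature_vocabulary):
            raise ValueError("W must have shape (t, d) matching the vocabulary")
        if self.lam < 0:
            raise ValueError("ridge penalty must be >= 0")

    @property
    def t(self) -> int:
        return self.W.shape[0]

    @property
    def d(self) -> int:
        return self.W.shape[1]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "W": self.W.tolist(),
            "feature_vocabulary": list(self.feature_vocabulary),
            "lambda": self.lam,
            "trait_names": list(self.trait_names),
            "mode": self.mode,
            "standardization": self.standardization.to_dict()
            if self.standardization
            else None,
        }
        path.write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "LinearTraitEstimator":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            W=np.asarray(d["W"], float),
            feature_vocabulary=tuple(d["feature_vocabulary"]),
            lam=float(d["lambda"]),
            trait_names=tuple(d.get("trait_names") or ()),
            mode=d.get("mode", "relative_frequency"),
            standardization=Standardization.from_dict(d["standardization"])
            if d.get("standardization")
            else None,
        )


def extract_features(
    tokens: Sequence[str],
    vocabulary: Sequence[str],
    mode: str = "relative_frequency",
    topic_loadings: Mapping[str, Sequence[float]] | None = None,
) -> FeatureVector:
    """Turn a token sequence into a feature vector over ``vocabulary``.

    relative_frequency
        Count in-vocabulary tokens and divide by the total in-vocabulary
        count; out-of-vocabulary tokens are ignored.  An all-OOV message
        yields the zero vector with ``empty=True``.
    topic_loading
        ``vocabulary`` names topics; each token's loading vector (rows of
        ``topic_loadings``) is averaged over in-vocabulary tokens.
    """
    if len(vocabulary) == 0:
        raise ValueError("feature vocabulary must be non-empty")
    d = len(vocabulary)
    if mode == "relative_frequency":
        index = {w: i for i, w in enumerate(vocabulary)}
        counts = np.zeros(d)
        for tok in tokens:
            i = index.get(tok)
            if i is not None:
                counts[i] += 1
        total = counts.sum()
        if total == 0:
            return FeatureVector(counts, empty=True)
        return FeatureVector(counts / total)
    elif mode == "topic_loading":
        if topic_loadings is None:
            raise ValueError("topic_loading mode requires a topic_loadings table")
        rows = [
            np.asarray(topic_loadings[tok], float)
            for tok in tokens
            if tok in topic_loadings
        ]
        if not rows:
            return FeatureVector(np.zeros(d), empty=True)
        mean = np.mean(rows, axis=0)
        if mean.shape[0] != d:
            raise ValueError("loading width does not match vocabulary size")
        return FeatureVector(mean)
    raise ValueError(f"unknown feature mode {mode!r}")


def participant_features(
    record: ParticipantRecord,
    vocabulary: Sequence[str],
    mode: str = "relative_frequency",
    topic_loadings: Mapping[str, Sequence[float]] | None = None,
) -> FeatureVector:
    """Pool all of a participant's messages into one feature vector.

    Pooling concatenates the messages before feature extraction (so relative
    frequencies are over the participant's full word count, not a mean of
    per-message frequencies).
    """
    pooled: list[str] = []
    for msg in record.messages:
        pooled.extend(msg)
    return extract_features(pooled, vocabulary, mode, topic_loadings)


def fit_participant_estimator(
    records: Sequence[ParticipantRecord],
    vocabulary: Sequence[str],
    lam: float = DEFAULT_RIDGE_LAMBDA,
    trait_names: Sequence[str] = (),
    mode: str = "relative_frequency",
    topic_loadings: Mapping[str, Sequence[float]] | None = None,
) -> LinearTraitEstimator:
    """Fit the per-dimension linear maps from participant features to scores.

    With ``lam > 0`` this is a ridge regression (no intercept); with
    ``lam == 0`` the least-squares problem is solved directly and a
    rank-deficient design yields the minimum-norm solution with a
    :class:`SingularFitWarning`.
    """
    if len(records) == 0:
        raise ValueError("need at least one participant record")
    if lam < 0:
        raise ValueError("ridge penalty must be >= 0")
    t = len(records[0].trait_scores)
    if any(len(r.trait_scores) != t for r in records):
        raise ValueError("inconsistent trait-score lengths across participants")
    X = np.stack(
        [participant_features(r, vocabulary, mode, topic_loadings).values for r in records]
    )
    Y = np.asarray([r.trait_scores for r in records], float)
    if lam == 0.0:
        W_T, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
        if rank < X.shape[1]:
            warnings.warn(
                "rank-deficient design with lambda=0; returning the "
                "minimum-norm least-squares solution",
                SingularFitWarning,
                stacklevel=2,
            )
        W = W_T.T
    else:
        model = Ridge(alpha=lam, fit_intercept=False, solver="cholesky")
        model.fit(X, Y)
        W = np.atleast_2d(model.coef_)
    return LinearTraitEstimator(
        W=W,
        feature_vocabulary=tuple(vocabulary),
        lam=lam,
        trait_names=tuple(trait_names),
        mode=mode,
    )


def score_message(estimator: LinearTraitEstimator, features: FeatureVector) -> np.ndarray:
    """Raw estimated trait vector for one message: ``W @ x``."""
    if features.d != estimator.d:
        raise ValueError(
            f"feature dimension {features.d} does not match estimator d={estimator.d}"
        )
    return estimator.W @ features.values


def score_corpus(
    estimator: LinearTraitEstimator,
    records: Sequence[CorpusRecord],
    spec: TraitSpec | None = None,
    topic_loadings: Mapping[str, Sequence[float]] | None = None,
) -> tuple[list[CorpusRecord], list[str]]:
    """Score every message and standardize over the corpus.

    Returns the records with ``scores_raw`` and ``scores_std`` filled, and
    the list of message ids whose features were all out-of-vocabulary (those
    receive the corpus-mean raw score).  Standardization constants are
    computed over the scored corpus and frozen into
    ``estimator.standardization`` for reuse at generation time.  A dimension
    with zero variance across the corpus is a configuration error.
    """
    if len(records) == 0:
        raise ValueError("cannot score an empty corpus")
    names = estimator.trait_names or (spec.names if spec else None)
    raw_rows: list[np.ndarray | None] = []
    flagged: list[str] = []
    for rec in records:
        tokens = rec.tokens if rec.tokens is not None else ()
        feats = extract_features(
            tokens, estimator.feature_vocabulary, estimator.mode, topic_loadings
        )
        if feats.empty:
            raw_rows.append(None)
            flagged.append(rec.message_id)
        else:
            raw_rows.append(score_message(estimator, feats))
    present = np.stack([r for r in raw_rows if r is not None])
    if present.shape[0] == 0:
        raise ValueError("every message in the corpus is out-of-vocabulary")
    mean_raw = present.mean(axis=0)
    raw = np.stack([r if r is not None else mean_raw for r in raw_rows])
    mu = raw.mean(axis=0)
    sd = raw.std(axis=0)
    for i, s in enumerate(sd):
        if s <= 0:
            name = names[i] if names else str(i)
            raise ValueError(
                f"estimated scores for dimension {name!r} have zero variance "
                "across the corpus; cannot standardize"
            )
    std = Standardization(mean=mu, sd=sd)
    estimator.standardization = std
    z = std.apply(raw)
    out = [
        replace(rec, scores_raw=tuple(raw[i]), scores_std=tuple(z[i]))
        for i, rec in enumerate(records)
    ]
    if flagged:
        logger.warning(
            "score_corpus: %d all-OOV messages received the corpus-mean score",
            len(flagged),
        )
    return out, flagged
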