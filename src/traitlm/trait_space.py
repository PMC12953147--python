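"""Trait-vector algebra.

Psychological trait profiles are vectors of continuous scores expressed in
standardized units (standard deviations above or below the population mean).
A profile such as ``(0, 0, +3, 0, 0)`` over the Big Five dimensions describes
an author three SDs above the mean in extraversion and average elsewhere.
This module provides construction, normalization, combination, and the
interpersonal-circumplex rotation between the warmth/dominance axes and the
extraversion/agreeableness axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Profiles are clamped to this range at construction.  Scores much beyond
#: three SDs are outside the operating range of a trained adapter (the usual
#: working range is [-3, +3], akin to a 7-point Likert scale), so a modest
#: hard bound guards against pathological inputs without affecting normal use.
SCORE_CLAMP = 5.0

#: Conventional rotation angle between the extraversion/agreeableness axes
#: and the warmth/dominance axes of the interpersonal circumplex, in degrees.
DEFAULT_CIRCUMPLEX_ALPHA = 22.5

BIG_FIVE = (
    "openness",
    "conscientiousness",
    "extraversion",
    "agreeableness",
    "neuroticism",
)


@dataclass(frozen=True)
class TraitSpec:
    """Named trait dimensions with raw-score population statistics.

    Parameters
    ----------
    names
        Ordered dimension labels; the ordering is authoritative everywhere
        (indices are 0-based).
    mu, sigma
        Per-dimension population mean and SD of the *raw* scores, used by
        :func:`standardize`.  Defaults are 0/1, i.e. scores already
        standardized.
    """

    names: tuple[str, ...]
    mu: tuple[float, ...] = ()
    sigma: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        names = tuple(self.names)
        mu = tuple(float(x) for x in (self.mu or (0.0,) * len(names)))
        sigma = tuple(float(x) for x in (self.sigma or (1.0,) * len(names)))
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        if len(names) == 0:
            raise ValueError("TraitSpec needs at least one dimension")
        if len(mu) != len(names) or len(sigma) != len(names):
            raise ValueError(
                f"mu/sigma lengths ({len(mu)}/{len(sigma)}) must match "
                f"number of dimensions ({len(names)})"
            )
        if any(not math.isfinite(m) for m in mu):
            raise ValueError("non-finite population mean")
        if any(s <= 0 or not math.isfinite(s) for s in sigma):
            raise ValueError("population SDs must be strictly positive")

    @property
    def t(self) -> int:
        return len(self.names)

    @classmethod
    def big_five(cls) -> "TraitSpec":
        return cls(names=BIG_FIVE)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_dict(self) -> dict:
        return {"names": list(self.names), "mu": list(self.mu), "sigma": list(self.sigma)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "TraitSpec":
        return cls(tuple(d["names"]), tuple(d.get("mu") or ()), tuple(d.get("sigma") or ()))


@dataclass(frozen=True)
class TraitProfile:
    """A standardized trait-score vector tied to a :class:`TraitSpec`."""

    spec: TraitSpec
    scores: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float).reshape(-1)
        if arr.shape[0] != self.spec.t:
            raise ValueError(
                f"profile length {arr.shape[0]} does not match spec.t={self.spec.t}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("trait scores must be finite")
        arr = np.clip(arr, -SCORE_CLAMP, SCORE_CLAMP)
        arr.flags.writeable = False
        object.__setattr__(self, "scores", arr)

    def __iter__(self):
        return iter(self.scores)

    def __len__(self) -> int:
        return self.spec.t

    def as_csv(self) -> str:
        return ",".join(format(x, "g") for x in self.scores)


@dataclass(frozen=True)
class CircumplexPoint:
    """A position on the interpersonal circumplex (warmth/dominance axes)."""

    warmth: float
    dominance: float
    alpha_degrees: float = DEFAULT_CIRCUMPLEX_ALPHA

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_degrees < 90.0):
            raise ValueError("alpha_degrees must lie in [0, 90)")


def build_input_vector(spec: TraitSpec, focal_index: int, k: float) -> TraitProfile:
    """Profile with score ``k`` on one dimension and 0 (the mean) elsewhere.

    This is the standard way of instructing the adapter to foreground a single
    trait: e.g. extraversion (index 2 of the Big Five) at ``k = +3`` yields
    ``(0, 0, 3, 0, 0)``.
    """
    if not isinstance(focal_index, (int, np.integer)) or isinstance(focal_index, bool):
        raise ValueError("focal_index must be an integer")
    if not 0 <= focal_index < spec.t:
        raise ValueError(f"focal_index {focal_index} out of range for t={spec.t}")
    if not math.isfinite(k):
        raise ValueError("k must be finite")
    scores = np.zeros(spec.t)
    scores[focal_index] = k
    return TraitProfile(spec, scores)


def combine_profiles(spec: TraitSpec, assignments: Mapping[int, float]) -> TraitProfile:
    """Profile carrying several focal scores at once, zero elsewhere.

    ``{0: +3, 2: -3}`` on the Big Five yields ``(3, 0, -3, 0, 0)`` — text both
    high in openness and low in extraversion.
    """
    scores = np.zeros(spec.t)
    seen: set[int] = set()
    for idx, k in assignments.items():
        if not 0 <= idx < spec.t:
            raise ValueError(f"index {idx} out of range for t={spec.t}")
        if idx in seen:
            raise ValueError(f"duplicate index {idx} in assignments")
        if not math.isfinite(k):
            raise ValueError("assigned scores must be finite")
        seen.add(idx)
        scores[idx] = k
    return TraitProfile(spec, scores)


def standardize(spec: TraitSpec, raw_scores: Sequence[float]) -> TraitProfile:
    """Convert raw scores to standardized units: ``(raw - mu) / sigma``."""
    raw = np.asarray(raw_scores, dtype=float).reshape(-1)
    if raw.shape[0] != spec.t:
        raise ValueError(f"raw score length {raw.shape[0]} != t={spec.t}")
    z = (raw - np.asarray(spec.mu)) / np.asarray(spec.sigma)
    return TraitProfile(spec, z)


def destandardize(spec: TraitSpec, profile: TraitProfile) -> np.ndarray:
    """Inverse of :func:`standardize`: ``mu + z * sigma`` (raw units)."""
    return np.asarray(spec.mu) + profile.scores * np.asarray(spec.sigma)


def circumplex_to_traits(point: CircumplexPoint) -> tuple[float, float]:
    """Rotate a warmth/dominance point onto extraversion/agreeableness axes.

    With rotation angle alpha::

        ext = cos(a) * warmth - sin(a) * dominance
        agr = sin(a) * warmth + cos(a) * dominance

    The rotation is orthonormal, so Euclidean norm is preserved.
    """
    a = math.radians(point.alpha_degrees)
    ext = math.cos(a) * point.warmth - math.sin(a) * point.dominance
    agr = math.sin(a) * point.warmth + math.cos(a) * point.dominance
    return ext, agr


def traits_to_circumplex(
    ext: float, agr: float, alpha_degrees: float = DEFAULT_CIRCUMPLEX_ALPHA
) -> CircumplexPoint:
    """Inverse rotation: extraversion/agreeableness back to warmth/dominance."""
    if not (0.0 <= alpha_degrees < 90.0):
        raise ValueError("alpha_degrees must lie in [0, 90)")
    a = math.radians(alpha_degrees)
    warmth = math.cos(a) * ext + math.sin(a) * agr
    dominance = -math.sin(a) * ext + math.cos(a) * agr
    return CircumplexPoint(warmth, dominance, alpha_degrees)
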