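"""Blinded level-matching evaluation.

A trained trait-conditioned generator is probed by sampling a *group* of
texts at each of several input levels of one trait (e.g. k = -3 / 0 / +3:
Low / Neutral / High), shuffling the groups, and asking a blinded rater to
match each group back to its level.  A rater's answer is a bijection from
presented groups to levels; it earns the fraction of groups assigned
correctly (fixed points of the permutation).  For three levels that is
exactly 1 (all correct), 1/3 (one correct — the other two necessarily
swapped), or 0; a uniformly random rater scores 1/m in expectation.

Human or LLM raters are replaced here by a programmatic *oracle rater*
that exploits the synthetic corpus's marker vocabulary: groups are ranked
by net marker frequency and levels assigned in rank order.  Agreement
between two raters over many trials is summarized by weighted Cohen's
kappa.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import cohen_kappa_score

from .adapter_lm import Checkpoint, GenerationRequest, generate
from .trait_space import TraitSpec, build_input_vector

THREE_LEVELS = (-3.0, 0.0, 3.0)
FIVE_LEVELS = (-3.0, -1.5, 0.0, 1.5, 3.0)


@dataclass(frozen=True)
class MatchingTrial:
    """One blinded instance: shuffled groups of generated samples plus the
    hidden group -> level assignment.

    ``groups[g]`` is the list of samples (token-string tuples) shown at
    presented position g; ``true_assignment[g]`` is the index into
    ``levels`` that actually generated it.
    """

    trait_index: int
    levels: tuple[float, ...]
    groups: tuple[tuple[tuple[str, ...], ...], ...]
    true_assignment: tuple[int, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.levels)) != len(self.levels) or len(self.levels) < 2:
            raise ValueError("need at least 2 distinct levels")
        if len(self.groups) != len(self.levels):
            raise ValueError("one group per level required")
        if sorted(self.true_assignment) != list(range(len(self.levels))):
            raise ValueError("true_assignment must be a permutation of the levels")
        sizes = {len(g) for g in self.groups}
        if len(sizes) != 1:
            raise ValueError("all groups must have the same size")


@dataclass(frozen=True)
class RaterAssignment:
    """A rater's answer: presented group g is claimed to be level
    ``levels[permutation[g]]``."""

    permutation: tuple[int, ...]

    def __post_init__(self) -> None:
        if sorted(self.permutation) != list(range(len(self.permutation))):
            raise ValueError("rater assignment must be a bijection over the levels")


def score_matching(assignment: RaterAssignment, trial: MatchingTrial) -> float:
    """Points in [0, 1]: the fraction of groups matched to their true level.

    On three levels the only attainable values are 0, 1/3 and 1 — a
    bijection on three elements cannot have exactly two fixed points.
    """
    if len(assignment.permutation) != len(trial.levels):
        raise ValueError("assignment size does not match trial levels")
    m = len(trial.levels)
    correct = sum(
        1 for g in range(m) if assignment.permutation[g] == trial.true_assignment[g]
    )
    return correct / m


def chance_baseline(m: int) -> float:
    """Expected points of a uniformly random bijective rater: 1/m.

    (The expected number of fixed points of a uniform random permutation is
    1 for every m, so the expected fixed-point *fraction* is 1/m — 33.33%
    for the three-level task.)
    """
    if m < 2:
        raise ValueError("need at least 2 levels")
    return 1.0 / m


def enumerate_chance_baseline(m: int) -> float:
    """Brute-force check of :func:`chance_baseline` over all m! permutations."""
    if m < 2:
        raise ValueError("need at least 2 levels")
    total = 0
    count = 0
    for perm in permutations(range(m)):
        total += sum(1 for i, p in enumerate(perm) if p == i)
        count += 1
    return total / (count * m)


def build_trials(
    checkpoint: Checkpoint,
    trait_index: int,
    levels: Sequence[float] = THREE_LEVELS,
    samples_per_group: int = 5,
    n_trials: int = 10,
    base_seed: int = 0,
    prompt: Sequence[str] = (),
    max_new_tokens: int = 16,
    policy: str = "topk",
) -> list[MatchingTrial]:
    """Generate the full blinded evaluation set for one trait dimension.

    Each trial uses its own generation seeds and an independently shuffled
    presentation order; everything is deterministic in ``base_seed``.
    """
    if not checkpoint.history:
        raise RuntimeError("checkpoint has no training history; train before evaluating")
    levels = tuple(float(k) for k in levels)
    if len(set(levels)) < 2:
        raise ValueError("need at least 2 distinct levels")
    spec = TraitSpec(
        checkpoint.trait_names
        or tuple(f"trait{i}" for i in range(checkpoint.adapter_cfg.latent_size))
    )
    prompt_ids = checkpoint.vocab.encode(tuple(prompt))
    trials = []
    for trial_i in range(n_trials):
        rng = np.random.default_rng((base_seed, trial_i))
        groups_by_level = []
        for li, k in enumerate(levels):
            profile = build_input_vector(spec, trait_index, k)
            samples = []
            for si in range(samples_per_group):
                req = GenerationRequest(
                    profile=profile,
                    prompt_tokens=prompt_ids,
                    max_new_tokens=max_new_tokens,
                    policy=policy,
                    seed=int(
                        np.random.default_rng(
                            (base_seed, trial_i, li, si)
                        ).integers(2**31)
                    ),
                )
                ids = generate(checkpoint, req)
                samples.append(checkpoint.vocab.decode(ids))
            groups_by_level.append(tuple(samples))
        order = rng.permutation(len(levels))
        trials.append(
            MatchingTrial(
                trait_index=trait_index,
                levels=levels,
                groups=tuple(groups_by_level[li] for li in order),
                true_assignment=tuple(int(x) for x in order),
                seed=trial_i,
            )
        )
    return trials


def oracle_rater(
    trial: MatchingTrial, marker_table: dict[int, dict[str, tuple[str, ...]]]
) -> RaterAssignment:
    """Deterministic stand-in for a human rater on synthetic vocabularies.

    Each presented group is scored by its mean net marker frequency for the
    trial's trait (frequency of high-pole markers minus low-pole markers);
    groups are ranked and levels assigned in rank order, ties broken by
    presented order (stable sort).
    """
    markers = marker_table[trial.trait_index]
    high, low = set(markers["high"]), set(markers["low"])
    net = []
    for group in trial.groups:
        n_tokens = sum(len(s) for s in group)
        if n_tokens == 0:
            net.append(0.0)
            continue
        n_hi = sum(1 for s in group for w in s if w in high)
        n_lo = sum(1 for s in group for w in s if w in low)
        net.append((n_hi - n_lo) / n_tokens)
    # presented groups in ascending net-marker order get ascending levels
    level_rank = np.argsort(trial.levels, kind="stable")
    group_rank = np.argsort(net, kind="stable")
    perm = [0] * len(trial.levels)
    for r, g in enumerate(group_rank):
        perm[int(g)] = int(level_rank[r])
    return RaterAssignment(tuple(perm))


class UndefinedKappaError(ValueError):
    """Kappa is undefined (empty input, or no observed variation to correct
    for chance against)."""


def weighted_kappa(
    ratings_a: Sequence,
    ratings_b: Sequence,
    weights: str = "linear",
    levels: Sequence | None = None,
) -> float:
    """Weighted Cohen's kappa between two raters over ordinal levels.

    ``weights`` is "linear" (default) or "quadratic".  Raises
    :class:`UndefinedKappaError` when agreement-by-chance is degenerate
    (e.g. both raters used a single identical category).
    """
    if weights not in ("linear", "quadratic"):
        raise ValueError("weights must be 'linear' or 'quadratic'")
    a = list(ratings_a)
    b = list(ratings_b)
    if len(a) != len(b):
        raise ValueError("rating vectors must have equal length")
    if len(a) == 0:
        raise UndefinedKappaError("kappa is undefined on empty ratings")
    if len(set(a)) == 1 and len(set(b)) == 1:
        raise UndefinedKappaError(
            "kappa is undefined when both raters use a single category"
        )
    labels = list(levels) if levels is not None else sorted(set(a) | set(b))
    kappa = cohen_kappa_score(a, b, labels=labels, weights=weights)
    if not math.isfinite(kappa):
        raise UndefinedKappaError("kappa is undefined for these ratings")
    return float(kappa)


def evaluation_report(
    trials_by_trait: dict[int, list[MatchingTrial]],
    assignments_by_trait: dict[int, list[RaterAssignment]],
    path: str | Path,
    rater_id: str = "oracle",
    trait_names: Sequence[str] | None = None,
) -> dict[int, float]:
    """Write a per-trial CSV report and return mean points per trait."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    means: dict[int, float] = {}
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["trial_id", "trait", "levels", "points", "rater_id"])
        for trait_index in sorted(trials_by_trait):
            trials = trials_by_trait[trait_index]
            assignments = assignments_by_trait[trait_index]
            points = [
                score_matching(assignment, trial)
                for trial, assignment in zip(trials, assignments)
            ]
            name = (
                trait_names[trait_index]
                if trait_names is not None
                else str(trait_index)
            )
            for trial, pt in zip(trials, points):
                writer.writerow(
                    [
                        trial.seed,
                        name,
                        ";".join(format(k, "g") for k in trial.levels),
                        format(pt, ".6f"),
                        rater_id,
                    ]
                )
            means[trait_index] = float(np.mean(points))
    return means
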