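"""Analytic chance level of the composite memory score under pure guessing.

A responder with no memory can still earn points: they may false-alarm on
item recognition (endorse an unseen object with confidence 1-3, earning
x in {1,2,3} pseudo-points) and then guess the correct side of the 2AFC
associative recognition with probability 1/2, earning y in {0,1,2,3}
points.  Associative recall contributes nothing at chance.  The expected
composite score of such a responder is

    C = p(FA) * sum_x p(x | FA) * ( x + 0.5 * sum_y p(y | FA & x) * y )

where p(FA) is the false-alarm rate on lures, p(x | FA) the distribution
of item pseudo-points given a false alarm (from the lure confidence
distribution), and p(y | FA & x) the distribution of
associative-recognition points given a chance response with x item points.
Because false alarms had no associative phase by design, p(y | FA & x) is
estimated from the studied trials' empirical (item points -> associative
points) contingency.

Per-participant C values are averaged into a group chance level used as
the null in the one-sample tests of :mod:`reinstate.stats`.  A vectorized
Monte-Carlo simulation of the same guessing process serves as an
independent oracle for the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .scoring import PointRule, score_item_recognition
from .types import ScoredTrial, TestTrial, ValidationError

__all__ = [
    "GuessingProfile",
    "estimate_guessing_profile",
    "chance_level_eq1",
    "monte_carlo_guessing_chance",
    "group_chance_level",
]

_X_LEVELS = np.array([1, 2, 3])
_Y_LEVELS = np.array([0, 1, 2, 3])
_ATOL = 1e-9


@dataclass(frozen=True)
class GuessingProfile:
    """Per-participant ingredients of the guessing chance level.

    ``p_x_given_fa`` indexes x = 1, 2, 3; ``p_y_given_fa_x`` is a 3 x 4
    matrix with rows x = 1, 2, 3 and columns y = 0, 1, 2, 3.  When
    ``p_fa = 0`` the conditionals are undefined and may be NaN; the chance
    level is 0 regardless.
    """

    p_fa: float
    p_x_given_fa: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))
    p_y_given_fa_x: np.ndarray = field(default_factory=lambda: np.full((3, 4), np.nan))
    participant_id: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "p_x_given_fa", np.asarray(self.p_x_given_fa, dtype=float))
        object.__setattr__(self, "p_y_given_fa_x", np.asarray(self.p_y_given_fa_x, dtype=float))
        if not 0.0 <= self.p_fa <= 1.0:
            raise ValidationError(f"p_fa must be in [0, 1], got {self.p_fa}")
        if self.p_x_given_fa.shape != (3,):
            raise ValidationError("p_x_given_fa must have shape (3,)")
        if self.p_y_given_fa_x.shape != (3, 4):
            raise ValidationError("p_y_given_fa_x must have shape (3, 4)")

    @property
    def is_degenerate(self) -> bool:
        """True when p_fa = 0 and the conditionals are undefined."""
        return self.p_fa == 0.0 and np.isnan(self.p_x_given_fa).all()

    def validate(self) -> None:
        """Check the distributions are proper (unless degenerate)."""
        if self.is_degenerate:
            return
        if np.isnan(self.p_x_given_fa).any() or not np.isclose(
            self.p_x_given_fa.sum(), 1.0, atol=_ATOL
        ):
            raise ValidationError(f"p_x_given_fa does not sum to 1: {self.p_x_given_fa}")
        if (self.p_x_given_fa < -_ATOL).any():
            raise ValidationError("p_x_given_fa has negative entries")
        row_sums = self.p_y_given_fa_x.sum(axis=1)
        if np.isnan(self.p_y_given_fa_x).any() or not np.allclose(row_sums, 1.0, atol=_ATOL):
            raise ValidationError(f"p_y_given_fa_x rows do not sum to 1: {row_sums}")
        if (self.p_y_given_fa_x < -_ATOL).any():
            raise ValidationError("p_y_given_fa_x has negative entries")


def estimate_guessing_profile(
    test_trials: Sequence[TestTrial],
    scored: Sequence[ScoredTrial],
    rule: PointRule = PointRule(),
) -> GuessingProfile:
    """Estimate one participant's guessing profile from their test data.

    ``p_fa`` and ``p_x_given_fa`` come from the lure responses (confidence
    1/2/3 -> pseudo-points 3/2/1); ``p_y_given_fa_x`` comes from the
    studied trials' empirical contingency of associative-recognition
    points given item points, row-normalized.  An x level never observed
    on studied trials falls back to the participant's marginal y
    distribution so C stays defined.
    """
    participants = {t.participant_id for t in test_trials} | {s.participant_id for s in scored}
    if len(participants) > 1:
        raise ValidationError(
            f"estimate_guessing_profile expects one participant, got {sorted(participants)}"
        )
    lures = [t for t in test_trials if t.is_lure]
    if not lures:
        raise ValidationError("cannot estimate a false-alarm rate without lures")
    pid = next(iter(participants)) if participants else None

    fa_pseudo = []
    for lure in lures:
        item = score_item_recognition(lure, rule)
        if item.is_false_alarm:
            fa_pseudo.append(item.fa_pseudo_points)
    p_fa = len(fa_pseudo) / len(lures)
    if p_fa == 0.0:
        return GuessingProfile(p_fa=0.0, participant_id=pid)

    counts_x = np.array([fa_pseudo.count(x) for x in _X_LEVELS], dtype=float)
    p_x = counts_x / counts_x.sum()

    # contingency of assoc points given item points on studied trials
    cont = np.zeros((3, 4))
    marginal = np.zeros(4)
    for s in scored:
        if s.item_points == 0:
            continue  # no associative phase followed a failed item answer
        cont[s.item_points - 1, s.assoc_points] += 1
        marginal[s.assoc_points] += 1
    if marginal.sum() == 0:
        raise ValidationError(
            "no studied trials with item points: cannot estimate p(y | FA & x)"
        )
    marginal = marginal / marginal.sum()
    p_y = np.empty((3, 4))
    for i in range(3):
        row_total = cont[i].sum()
        p_y[i] = cont[i] / row_total if row_total > 0 else marginal
    return GuessingProfile(p_fa=p_fa, p_x_given_fa=p_x, p_y_given_fa_x=p_y, participant_id=pid)


def chance_level_eq1(profile: GuessingProfile) -> float:
    """Closed-form expected guessing score C in [0, 4.5].

    C = p(FA) * sum_x p(x|FA) * (x + 0.5 * sum_y p(y|FA & x) * y); the 0.5
    is the 2AFC probability of guessing the correct side, and associative
    recall contributes 0 at chance.
    """
    if profile.p_fa == 0.0:
        return 0.0
    profile.validate()
    inner = _X_LEVELS + 0.5 * (profile.p_y_given_fa_x @ _Y_LEVELS.astype(float))
    return float(profile.p_fa * (profile.p_x_given_fa @ inner))


def monte_carlo_guessing_chance(
    profile: GuessingProfile,
    n_trials: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Simulate a memory-free responder and return the mean trial score.

    Independent oracle for :func:`chance_level_eq1`: per trial, a false
    alarm occurs with probability ``p_fa``; given one, x pseudo-points are
    drawn from ``p_x_given_fa`` and, with probability 1/2 (a correct 2AFC
    side guess), y points from ``p_y_given_fa_x``; otherwise y = 0.
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if profile.p_fa == 0.0:
        return 0.0
    profile.validate()
    fa = rng.random(n_trials) < profile.p_fa
    n_fa = int(fa.sum())
    if n_fa == 0:
        return 0.0
    x = rng.choice(_X_LEVELS, size=n_fa, p=profile.p_x_given_fa)
    correct_side = rng.random(n_fa) < 0.5
    # draw y per trial from the row of its x via inverse-CDF on one uniform
    cdf = np.cumsum(profile.p_y_given_fa_x, axis=1)
    u = rng.random(n_fa)
    y = (u[:, None] > cdf[x - 1]).sum(axis=1)
    y = np.where(correct_side, _Y_LEVELS[np.clip(y, 0, 3)], 0)
    return float((x + y).sum() / n_trials)


def group_chance_level(profiles: Iterable[GuessingProfile]) -> float:
    """Unweighted mean of per-participant chance levels C."""
    values = [chance_level_eq1(p) for p in profiles]
    if not values:
        raise ValidationError("group_chance_level needs at least one profile")
    return float(np.mean(values))


def profiles_from_tables(
    test_trials: Sequence[TestTrial],
    scored: Sequence[ScoredTrial],
    rule: PointRule = PointRule(),
) -> list[GuessingProfile]:
    """Per-participant guessing profiles from pooled multi-participant tables."""
    by_pid_trials: dict = {}
    by_pid_scored: dict = {}
    for t in test_trials:
        by_pid_trials.setdefault(t.participant_id, []).append(t)
    for s in scored:
        by_pid_scored.setdefault(s.participant_id, []).append(s)
    return [
        estimate_guessing_profile(by_pid_trials[pid], by_pid_scored.get(pid, []), rule)
        for pid in sorted(by_pid_trials)
    ]
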