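"""Composite 0-9 memory score for the three-part memory test.

Each studied object went through up to three phases: item recognition
(6-point confidence, 1 = "very sure I have seen it"), cued associative
recall of the scene (two independent raters, 0 / 0.5 / 1 each), and 2AFC
associative recognition of the scene (6-point confidence over left/right).
Each phase is worth 0-3 points and the composite is their sum, so a trial
scores between 0 (item recognition failed) and 9 (everything correct at
the highest confidence).

Point rules:

* item recognition — confidence 1 -> 3, 2 -> 2, 3 -> 1 points; confidence
  4-6 ("not seen") or a timeout -> 0.  On lures, confidence 1-3 is a false
  alarm; false alarms never earn memory points but their confidence maps
  to pseudo-points 3/2/1 used by the guessing chance-level model.
* associative recall — 3 x mean of the two rater scores, giving
  {0, 0.75, 1.5, 2.25, 3}.
* associative recognition — confidence 1-3 picks the left scene, 4-6 the
  right; a wrong side or a timeout scores 0, a correct side scores 3/2/1
  points for the outer/middle/inner confidence bands ({1,6} / {2,5} /
  {3,4}).

Gating: recall and associative recognition only happened after a correct
item answer, so ``item_points = 0`` forces the composite to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .types import ScoredTrial, TestTrial, ValidationError

__all__ = [
    "PointRule",
    "ItemScore",
    "score_item_recognition",
    "score_associative_recall",
    "score_associative_recognition",
    "compute_memory_score",
    "score_test_trials",
]

# confidence -> points for a correct answer; decreasing confidence, fewer points
_ITEM_POINTS: Mapping[int, int] = {1: 3, 2: 2, 3: 1, 4: 0, 5: 0, 6: 0}
# associative recognition: confidence band -> points (outer = most confident)
_ASSOC_BAND_POINTS: Mapping[int, int] = {1: 3, 2: 2, 3: 1, 4: 1, 5: 2, 6: 3}
_RECALL_VALUES = (0.0, 0.5, 1.0)


@dataclass(frozen=True)
class PointRule:
    """The confidence -> points maps; defaults encode the rules above."""

    item_map: Mapping[int, int] = field(default_factory=lambda: dict(_ITEM_POINTS))
    assoc_band_map: Mapping[int, int] = field(default_factory=lambda: dict(_ASSOC_BAND_POINTS))
    recall_weight: float = 3.0


@dataclass(frozen=True)
class ItemScore:
    points: int
    is_false_alarm: bool
    fa_pseudo_points: Optional[int]  # 3/2/1 for lure confidence 1/2/3


def score_item_recognition(trial: TestTrial, rule: PointRule = PointRule()) -> ItemScore:
    """Score the item-recognition phase of one trial (lure or studied).

    Studied objects earn 3/2/1 points for confidence 1/2/3 and 0 for 4-6 or
    a timeout.  Lures earn 0 points always; endorsing a lure (confidence
    1-3) is a false alarm whose confidence is recorded as pseudo-points.
    """
    conf = trial.item_confidence
    if trial.is_lure:
        if conf is not None and conf in (1, 2, 3):
            return ItemScore(points=0, is_false_alarm=True, fa_pseudo_points=rule.item_map[conf])
        return ItemScore(points=0, is_false_alarm=False, fa_pseudo_points=None)
    if conf is None:
        return ItemScore(points=0, is_false_alarm=False, fa_pseudo_points=None)
    return ItemScore(points=rule.item_map[conf], is_false_alarm=False, fa_pseudo_points=None)


def score_associative_recall(
    rater1: Optional[float], rater2: Optional[float], rule: PointRule = PointRule()
) -> float:
    """3 x mean rater score.  One absent rater duplicates the other;
    both absent (no recall phase / empty answer unrated) scores 0."""
    if rater1 is None and rater2 is None:
        return 0.0
    if rater1 is None:
        rater1 = rater2
    if rater2 is None:
        rater2 = rater1
    for value in (rater1, rater2):
        if value not in _RECALL_VALUES:
            raise ValidationError(f"rater scores must be 0, 0.5 or 1, got {value!r}")
    return rule.recall_weight * (rater1 + rater2) / 2.0


def score_associative_recognition(trial: TestTrial, rule: PointRule = PointRule()) -> int:
    """Score the 2AFC associative-recognition phase of one studied trial."""
    if trial.is_lure:
        raise ValidationError("lures have no associative-recognition phase")
    conf = trial.assoc_confidence
    if conf is None or trial.assoc_correct_side is None:
        return 0
    chosen = "left" if conf <= 3 else "right"
    if chosen != trial.assoc_correct_side:
        return 0
    return rule.assoc_band_map[conf]


def compute_memory_score(
    trial: TestTrial,
    rule: PointRule = PointRule(),
    congruency_bin: Optional[str] = None,
    reactivation_level: Optional[int] = None,
) -> ScoredTrial:
    """Combine the three phase scores into the 0-9 composite for one trial.

    Failed item recognition (0 points: wrong answer or timeout) gates the
    whole trial to 0 because the later phases only followed a correct item
    answer.  Lures are rejected — they are scored only by
    :func:`score_item_recognition` and feed the chance-level model instead.
    """
    if trial.is_lure:
        raise ValidationError(
            f"lure {trial.object_id!r} has no composite memory score; "
            "score it with score_item_recognition"
        )
    item = score_item_recognition(trial, rule)
    if item.points == 0:
        recall_points, assoc_points = 0.0, 0
    else:
        recall_points = score_associative_recall(trial.recall_rater1, trial.recall_rater2, rule)
        assoc_points = score_associative_recognition(trial, rule)
    return ScoredTrial(
        participant_id=trial.participant_id,
        triad_id=trial.triad_id,
        item_points=item.points,
        recall_points=recall_points,
        assoc_points=assoc_points,
        memory_score=item.points + recall_points + assoc_points,
        congruency_bin=congruency_bin,
        reactivation_level=reactivation_level,
    )


def score_test_trials(
    trials: Iterable[TestTrial],
    rule: PointRule = PointRule(),
    congruency_bins: Optional[Mapping[tuple, str]] = None,
    reactivation_levels: Optional[Mapping[tuple, int]] = None,
) -> tuple[list[ScoredTrial], pd.DataFrame]:
    """Score all studied trials and tabulate lure outcomes.

    ``congruency_bins`` / ``reactivation_levels`` map
    ``(participant_id, triad_id)`` to the bin/level to attach.  Returns the
    scored studied trials and a lure table with columns ``participant_id``,
    ``object_id``, ``is_false_alarm``, ``fa_pseudo_points``.
    """
    scored: list[ScoredTrial] = []
    lure_rows = []
    for trial in trials:
        if trial.is_lure:
            item = score_item_recognition(trial, rule)
            lure_rows.append(
                {
                    "participant_id": trial.participant_id,
                    "object_id": trial.object_id,
                    "is_false_alarm": item.is_false_alarm,
                    "fa_pseudo_points": item.fa_pseudo_points,
                }
            )
            continue
        key = (trial.participant_id, trial.triad_id)
        scored.append(
            compute_memory_score(
                trial,
                rule,
                congruency_bin=(congruency_bins or {}).get(key),
                reactivation_level=(reactivation_levels or {}).get(key),
            )
        )
    lures = pd.DataFrame(
        lure_rows, columns=["participant_id", "object_id", "is_false_alarm", "fa_pseudo_points"]
    )
    return scored, lures
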