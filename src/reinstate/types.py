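"""Domain records shared across the behavioral and imaging stages.

The experiment couples three behavioral tables (encoding trials with
subjective reactivation reports, a three-part memory test, and post-hoc
congruency ratings) to voxel-pattern data.  Records are plain dataclasses;
table-level work is done on :class:`pandas.DataFrame` views produced by
:mod:`reinstate.io`.

Missing responses (timeouts) are represented as ``None`` / ``NaN`` and are
never silently coerced to zero: a timeout scores zero points but remains
distinguishable from an explicit response in every table round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "EncodingTrial",
    "TestTrial",
    "CongruencyRating",
    "ScoredTrial",
    "PatternDataset",
    "ValidationError",
]


class ValidationError(ValueError):
    """A record or table violates a domain invariant."""


@dataclass(frozen=True)
class EncodingTrial:
    """One AC-encoding event with the subjective B-reactivation report.

    ``reactivation_response`` is the 3-level button report given while
    learning the AC pair (3 = strong, 2 = a bit, 1 = none); ``None`` means
    the participant did not press a button within the 3 s response window.
    """

    participant_id: str
    triad_id: int
    designed_congruency: str  # "congruent" | "incongruent" (stimulus-set assignment)
    reactivation_response: Optional[int] = None  # 1 | 2 | 3 | None
    reaction_time: Optional[float] = None  # seconds

    def __post_init__(self) -> None:
        if self.designed_congruency not in ("congruent", "incongruent"):
            raise ValidationError(
                f"designed_congruency must be 'congruent' or 'incongruent', "
                f"got {self.designed_congruency!r}"
            )
        if self.reactivation_response is not None and self.reactivation_response not in (1, 2, 3):
            raise ValidationError(
                f"reactivation_response must be 1, 2, 3 or missing, "
                f"got {self.reactivation_response!r}"
            )
        if self.reaction_time is not None and self.reaction_time < 0:
            raise ValidationError(f"reaction_time must be >= 0, got {self.reaction_time}")


@dataclass(frozen=True)
class TestTrial:
    """One memory-test trial (studied object or lure).

    Item recognition uses a 6-point confidence scale: 1 = "very sure I have
    seen it" ... 6 = "very sure I have not seen it".  Lures carry no recall
    or associative-recognition fields (the test skipped those phases).
    Associative recognition is a 2AFC with the same 6-point scale: 1-3 pick
    the left scene, 4-6 the right, with confidence decreasing towards the
    middle of the scale.
    """

    participant_id: str
    object_id: str
    is_lure: bool
    triad_id: Optional[int] = None
    item_confidence: Optional[int] = None  # 1..6 or missing (timeout)
    recall_rater1: Optional[float] = None  # 0 | 0.5 | 1
    recall_rater2: Optional[float] = None
    assoc_confidence: Optional[int] = None  # 1..6 or missing
    assoc_correct_side: Optional[str] = None  # "left" | "right"

    def __post_init__(self) -> None:
        if self.is_lure:
            if self.triad_id is not None:
                raise ValidationError(f"lure {self.object_id!r} must not carry a triad_id")
            for name in ("recall_rater1", "recall_rater2", "assoc_confidence", "assoc_correct_side"):
                if getattr(self, name) is not None:
                    raise ValidationError(
                        f"lure {self.object_id!r} must not carry {name} (lures have no "
                        "recall/associative phase)"
                    )
        else:
            if self.triad_id is None:
                raise ValidationError(f"non-lure {self.object_id!r} requires a triad_id")
        for name in ("item_confidence", "assoc_confidence"):
            value = getattr(self, name)
            if value is not None and value not in (1, 2, 3, 4, 5, 6):
                raise ValidationError(f"{name} must be in 1..6 or missing, got {value!r}")
        for name in ("recall_rater1", "recall_rater2"):
            value = getattr(self, name)
            if value is not None and value not in (0.0, 0.5, 1.0):
                raise ValidationError(f"{name} must be 0, 0.5 or 1, got {value!r}")
        if self.assoc_correct_side is not None and self.assoc_correct_side not in ("left", "right"):
            raise ValidationError(
                f"assoc_correct_side must be 'left' or 'right', got {self.assoc_correct_side!r}"
            )


@dataclass(frozen=True)
class CongruencyRating:
    """Post-hoc subjective congruency of one scene-object pair, 1-5."""

    participant_id: str
    triad_id: int
    rating: int

    def __post_init__(self) -> None:
        if self.rating not in (1, 2, 3, 4, 5):
            raise ValidationError(f"rating must be in 1..5, got {self.rating!r}")


@dataclass(frozen=True)
class ScoredTrial:
    """One scored memory-test trial with its three point components.

    ``memory_score = item_points + recall_points + assoc_points`` with the
    gating rule that a failed item recognition (0 points) forces the total
    to 0 (the later test phases only followed a correct item answer).
    """

    participant_id: str
    triad_id: int
    item_points: int  # 0..3
    recall_points: float  # 0, 0.75, 1.5, 2.25, 3
    assoc_points: int  # 0..3
    memory_score: float  # 0..9
    congruency_bin: Optional[str] = None  # "incongruent" | "excluded" | "congruent"
    reactivation_level: Optional[int] = None  # 1 | 2 | 3

    def __post_init__(self) -> None:
        if self.item_points not in (0, 1, 2, 3):
            raise ValidationError(f"item_points must be in 0..3, got {self.item_points!r}")
        if self.assoc_points not in (0, 1, 2, 3):
            raise ValidationError(f"assoc_points must be in 0..3, got {self.assoc_points!r}")
        if self.recall_points not in (0.0, 0.75, 1.5, 2.25, 3.0):
            raise ValidationError(
                f"recall_points must be in {{0, 0.75, 1.5, 2.25, 3}}, got {self.recall_points!r}"
            )
        expected = self.item_points + self.recall_points + self.assoc_points
        if abs(self.memory_score - expected) > 1e-12:
            raise ValidationError(
                f"memory_score {self.memory_score} != sum of components {expected}"
            )
        if self.item_points == 0 and self.memory_score != 0:
            raise ValidationError("item_points = 0 gates the memory score to 0")
        if self.congruency_bin is not None and self.congruency_bin not in (
            "incongruent",
            "excluded",
            "congruent",
        ):
            raise ValidationError(f"bad congruency_bin {self.congruency_bin!r}")
        if self.reactivation_level is not None and self.reactivation_level not in (1, 2, 3):
            raise ValidationError(f"bad reactivation_level {self.reactivation_level!r}")


@dataclass
class PatternDataset:
    """A scan x voxel matrix with per-scan metadata and the event table.

    ``data`` holds one row per acquired volume, restricted to in-mask
    voxels.  ``scan_meta`` has one row per volume with columns ``run``,
    ``volume`` (0-based index within its run), ``condition`` (stimulus class
    during that volume or ``"rest"``), ``block`` (block/event id or -1) and
    ``onset`` (0-based onset volume index of that block, or -1).
    ``events`` has one row per block/event: ``run``, ``block``,
    ``condition``, ``onset`` (seconds), ``duration`` (seconds),
    ``onset_index`` (0-based volume index, floor(onset / tr)).

    Volume indices are 0-based throughout; a volume "3 TRs after onset" is
    ``onset_index + 3`` (the 4th volume of the block in 1-based counting).
    """

    data: np.ndarray
    scan_meta: pd.DataFrame
    events: pd.DataFrame
    tr: float
    voxel_index: Optional[np.ndarray] = None  # (n_voxels, 3) mask coordinates
    flagged_voxels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be a 2-D scan x voxel matrix")
        if len(self.scan_meta) != self.data.shape[0]:
            raise ValidationError(
                f"scan_meta has {len(self.scan_meta)} rows for {self.data.shape[0]} scans"
            )
        if self.tr <= 0:
            raise ValidationError(f"tr must be positive, got {self.tr}")
        if self.flagged_voxels.size == 0:
            self.flagged_voxels = np.zeros(self.data.shape[1], dtype=bool)

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def runs(self) -> list:
        return list(pd.unique(self.scan_meta["run"]))

    def run_slice(self, run) -> np.ndarray:
        """Boolean row mask for one run."""
        return (self.scan_meta["run"] == run).to_numpy()
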