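"""Synthetic AB-AC behavioral tables and block-design voxel patterns.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised and validated without access to
scanner data:

* 120 ABC triads per participant, counterbalanced congruent/incongruent
  by design, with a 3-level subjective reactivation report;
* the three-part memory test (item recognition with 6-point confidence,
  two-rater associative recall, 2AFC associative recognition) plus 60
  lures answered from a guessing profile;
* 1-5 congruency ratings clustered around the designed condition with
  some indifferent "3" responses;
* a two-run scene/object/face localizer (12 s blocks, 7 s ITI, TR 2 s)
  with class-specific multivoxel patterns, low-frequency drift and white
  noise;
* an AC-encoding run in which each event reinstates the scene pattern at
  onset + 3 volumes with amplitude increasing in the trial's reactivation
  level (gain ``gamma``; ``gamma = 0`` gives a null dataset).

Behavioral model (ordered-threshold / cumulative-link throughout): each
trial has a latent association strength ``s = mu + beta_c * congruent +
noise``; the reactivation report ``r`` comes from thresholds on ``s`` plus
noise; the latent memory strength ``m`` adds participant intercepts and
the reactivation/congruency effects ``beta_r * (r - 1) + beta_cr *
(r - 1) * congruent``; all test responses are thresholded or logistic
functions of ``m``.  Hemodynamics are modelled as a fixed 2-volume boxcar
shift — the analyses only ever read volumes at fixed TR offsets, so a
shift is sufficient and keeps the generator analytically transparent.

Default effect sizes and thresholds were calibrated once so the six
(congruency x reactivation) cell means reproduce the qualitative pattern
of the study (congruent above incongruent at every reactivation level,
means rising with reactivation, roughly spanning 1.5-6 of the 0-9 scale)
and then frozen; they are not estimates of the real effect magnitudes.
The default lure false-alarm rate (0.171) and its confidence split
(8.8% / 4.8% / 3.5% of lures at 1 / 2 / 3 pseudo-points) follow the
group-level rates the study reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    CongruencyRating,
    EncodingTrial,
    PatternDataset,
    TestTrial,
    ValidationError,
)

__all__ = ["SyntheticConfig", "simulate_behavior", "simulate_localizer", "simulate_ac_encoding"]

CLASSES = ("scene", "object", "face")


@dataclass(frozen=True)
class SyntheticConfig:
    """All generative parameters; defaults are the frozen study-shaped set."""

    # design
    n_participants: int = 25
    n_triads: int = 120  # half congruent by design
    n_lures: int = 60

    # behavioral latent model
    mu: float = 0.0  # baseline association strength
    beta_c: float = 1.2  # congruency effect on latent strength
    beta_r: float = 0.45  # reactivation -> memory coupling (per level step)
    beta_cr: float = 0.25  # congruency x reactivation interaction
    sigma: float = 1.0  # trial noise on latent strength
    sigma_react: float = 1.0  # noise on the reactivation report latent
    react_coupling: float = 0.35  # weight of latent strength in the report
    sigma_memory: float = 0.9  # trial noise on latent memory strength
    participant_sd: float = 0.3  # random intercept SD across participants
    strength_to_memory: float = 0.55  # carry-over of s into m

    # response thresholds (ordered-threshold models)
    react_thresholds: tuple = (-0.45, 0.6)  # r = 1 / 2 / 3
    item_thresholds: tuple = (-1.4, -0.7, 0.0, 0.9, 1.8)  # confidence 6..1
    recall_thresholds: tuple = (1.5, 2.4)  # rater 0 / 0.5 / 1
    sigma_rater: float = 0.5
    assoc_offset: float = 0.5  # logistic midpoint for a correct 2AFC side
    assoc_scale: float = 1.0
    assoc_band_thresholds: tuple = (1.0, 2.0)  # confidence band 1 / 2 / 3
    congruency_separation: float = 1.1
    congruency_noise: float = 0.7
    rating_thresholds: tuple = (-1.6, -0.5, 0.5, 1.6)  # ratings 1..5
    p_react_missing: float = 0.02
    p_item_missing: float = 0.01
    p_assoc_missing: float = 0.02

    # lure guessing profile
    p_fa: float = 0.171
    p_fa_conf: tuple = (0.035 / 0.171, 0.048 / 0.171, 0.088 / 0.171)  # conf 1 / 2 / 3
    p_cr_conf: tuple = (0.2, 0.3, 0.5)  # correct rejections: conf 4 / 5 / 6

    # voxel-pattern model
    n_voxels: int = 500
    n_signal_voxels: int = 250
    blocks_per_class: int = 10  # across all localizer runs
    n_localizer_runs: int = 2
    block_duration: float = 12.0  # seconds
    iti: float = 7.0  # seconds between localizer blocks
    tr: float = 2.0
    snr: float = 2.0  # signal amplitude / noise SD
    noise_sd: float = 1.0
    drift_amplitude: float = 1.0
    hemodynamic_delay: int = 2  # volumes
    gamma: float = 1.0  # reinstatement gain: amplitude = gamma * (r - 1) / 2
    reinstatement_noise: float = 0.15  # SD of event amplitude jitter
    ac_trial_spacing: float = 12.0  # seconds between AC events
    lead_in: float = 10.0  # seconds of rest at run start

    seed: int = 0

    def __post_init__(self):
        for name in ("n_participants", "n_triads", "n_lures", "n_voxels",
                     "n_signal_voxels", "blocks_per_class", "n_localizer_runs"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.sigma <= 0 or self.snr < 0 or self.noise_sd <= 0:
            raise ValidationError("sigma and noise_sd must be positive, snr >= 0")
        if self.n_signal_voxels > self.n_voxels:
            raise ValidationError("n_signal_voxels cannot exceed n_voxels")
        for name in ("react_thresholds", "item_thresholds", "recall_thresholds",
                     "assoc_band_thresholds", "rating_thresholds"):
            t = getattr(self, name)
            if list(t) != sorted(t):
                raise ValidationError(f"{name} must be ascending: {t}")
        for p in (self.p_fa, self.p_react_missing, self.p_item_missing, self.p_assoc_missing):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent seeded stream per component (behavior / localizer /
        AC patterns use streams 1 / 2 / 3)."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


_BEHAVIOR_STREAM, _LOCALIZER_STREAM, _AC_STREAM = 1, 2, 3


def _ordinal(latent: np.ndarray, thresholds: Sequence[float]) -> np.ndarray:
    """1-based ordered-threshold category: 1 + #(latent > threshold)."""
    return 1 + np.searchsorted(np.asarray(thresholds), latent, side="left").astype(int)


def simulate_behavior(
    cfg: SyntheticConfig = SyntheticConfig(),
) -> tuple[list[EncodingTrial], list[TestTrial], list[CongruencyRating], pd.DataFrame]:
    """Generate the three behavioral tables plus the latent truth table.

    The truth table has one row per studied triad with columns
    ``participant_id``, ``triad_id``, ``congruent`` (designed, 0/1),
    ``s`` (latent strength), ``r`` (underlying reactivation level),
    ``m`` (latent memory strength) and ``rating``.
    """
    rng = cfg.rng(_BEHAVIOR_STREAM)
    encoding: list[EncodingTrial] = []
    test: list[TestTrial] = []
    ratings: list[CongruencyRating] = []
    truth_rows = []

    half = cfg.n_triads // 2
    for p in range(cfg.n_participants):
        pid = f"sub-{p + 1:02d}"
        alpha = rng.normal(0.0, cfg.participant_sd)
        congruent = np.zeros(cfg.n_triads, dtype=int)
        congruent[rng.permutation(cfg.n_triads)[:half]] = 1

        s = cfg.mu + cfg.beta_c * congruent + rng.normal(0.0, cfg.sigma, cfg.n_triads)
        r = _ordinal(
            cfg.react_coupling * s + rng.normal(0.0, cfg.sigma_react, cfg.n_triads),
            cfg.react_thresholds,
        )
        react_missing = rng.random(cfg.n_triads) < cfg.p_react_missing
        m = (
            alpha
            + cfg.strength_to_memory * s
            + cfg.beta_r * (r - 1)
            + cfg.beta_cr * (r - 1) * congruent
            + rng.normal(0.0, cfg.sigma_memory, cfg.n_triads)
        )

        item_conf = 7 - _ordinal(m, cfg.item_thresholds)  # high m -> confidence 1
        item_missing = rng.random(cfg.n_triads) < cfg.p_item_missing
        hit = (~item_missing) & (item_conf <= 3)

        rater1 = (_ordinal(m + rng.normal(0.0, cfg.sigma_rater, cfg.n_triads),
                           cfg.recall_thresholds) - 1) / 2.0
        rater2 = (_ordinal(m + rng.normal(0.0, cfg.sigma_rater, cfg.n_triads),
                           cfg.recall_thresholds) - 1) / 2.0

        p_correct = 0.5 + 0.5 / (1.0 + np.exp(-(m - cfg.assoc_offset) / cfg.assoc_scale))
        side_correct = rng.random(cfg.n_triads) < p_correct
        band = _ordinal(m, cfg.assoc_band_thresholds)  # 1 (low conf) .. 3 (high conf)
        correct_side = np.where(rng.random(cfg.n_triads) < 0.5, "left", "right")
        chosen_side = np.where(side_correct, correct_side,
                               np.where(correct_side == "left", "right", "left"))
        # left -> confidence 3/2/1 for band 1/2/3; right -> 4/5/6
        assoc_conf = np.where(chosen_side == "left", 4 - band, 3 + band)
        assoc_missing = rng.random(cfg.n_triads) < cfg.p_assoc_missing

        lat = (2 * congruent - 1) * cfg.congruency_separation + rng.normal(
            0.0, cfg.congruency_noise, cfg.n_triads
        )
        rating = _ordinal(lat, cfg.rating_thresholds)

        rt = np.round(0.5 + rng.gamma(2.0, 0.5, cfg.n_triads), 3)
        for t in range(cfg.n_triads):
            triad = t + 1
            encoding.append(
                EncodingTrial(
                    participant_id=pid,
                    triad_id=triad,
                    designed_congruency="congruent" if congruent[t] else "incongruent",
                    reactivation_response=None if react_missing[t] else int(r[t]),
                    reaction_time=None if react_missing[t] else float(min(rt[t], 3.0)),
                )
            )
            test.append(
                TestTrial(
                    participant_id=pid,
                    object_id=f"obj-{triad:03d}",
                    is_lure=False,
                    triad_id=triad,
                    item_confidence=None if item_missing[t] else int(item_conf[t]),
                    recall_rater1=float(rater1[t]) if hit[t] else None,
                    recall_rater2=float(rater2[t]) if hit[t] else None,
                    assoc_confidence=(
                        int(assoc_conf[t]) if hit[t] and not assoc_missing[t] else None
                    ),
                    assoc_correct_side=str(correct_side[t]) if hit[t] else None,
                )
            )
            ratings.append(CongruencyRating(participant_id=pid, triad_id=triad,
                                            rating=int(rating[t])))
            truth_rows.append(
                {
                    "participant_id": pid,
                    "triad_id": triad,
                    "congruent": int(congruent[t]),
                    "s": float(s[t]),
                    "r": int(r[t]),
                    "m": float(m[t]),
                    "rating": int(rating[t]),
                }
            )

        # lures: guessing profile only
        is_fa = rng.random(cfg.n_lures) < cfg.p_fa
        fa_conf = rng.choice([1, 2, 3], size=cfg.n_lures, p=np.asarray(cfg.p_fa_conf))
        cr_conf = rng.choice([4, 5, 6], size=cfg.n_lures, p=np.asarray(cfg.p_cr_conf))
        for j in range(cfg.n_lures):
            test.append(
                TestTrial(
                    participant_id=pid,
                    object_id=f"lure-{j + 1:03d}",
                    is_lure=True,
                    item_confidence=int(fa_conf[j]) if is_fa[j] else int(cr_conf[j]),
                )
            )

    return encoding, test, ratings, pd.DataFrame(truth_rows)


def _block_order(n_blocks_per_class: int, rng: np.random.Generator) -> list[str]:
    """Pseudorandom class order with no immediate same-class repeats."""
    order: list[str] = []
    for _ in range(n_blocks_per_class):
        triple = list(rng.permutation(list(CLASSES)))
        while order and triple[0] == order[-1]:
            triple = list(rng.permutation(list(CLASSES)))
        order.extend(triple)
    return order


def _noise_and_drift(n_vol: int, cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    noise = rng.normal(0.0, cfg.noise_sd, size=(n_vol, cfg.n_voxels))
    t = np.arange(n_vol)
    for k in range(1, 4):  # slow cosines, periods >= 2/3 of the run
        phase = np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_vol))
        noise += cfg.drift_amplitude * phase[:, None] * rng.normal(0.0, 1.0, cfg.n_voxels)
    return noise


def _class_patterns(cfg: SyntheticConfig, rng: np.random.Generator) -> dict:
    """Fixed multivoxel pattern per class over the signal voxel set.

    Scene and face take opposite-signed values at every signal voxel
    (random sign and magnitude per voxel), so each signal voxel carries
    genuine scene-vs-face contrast and the set is recoverable by the
    between-class F statistic; the object pattern is an independent draw.
    """
    signal_voxels = rng.permutation(cfg.n_voxels)[: cfg.n_signal_voxels]
    contrast = rng.uniform(0.5, 1.5, cfg.n_signal_voxels) * rng.choice(
        [-1.0, 1.0], cfg.n_signal_voxels
    )
    patterns = {}
    for cls, values in (
        ("scene", contrast),
        ("face", -contrast),
        ("object", rng.normal(0.0, 1.0, cfg.n_signal_voxels)),
    ):
        pattern = np.zeros(cfg.n_voxels)
        pattern[signal_voxels] = values
        patterns[cls] = pattern
    return {"signal_voxels": np.sort(signal_voxels), "patterns": patterns}


def simulate_localizer(
    cfg: SyntheticConfig = SyntheticConfig(),
) -> tuple[PatternDataset, np.ndarray]:
    """Block-design localizer patterns plus the ground-truth signal voxels.

    ``cfg.blocks_per_class`` blocks of each of scene/object/face are spread
    evenly over ``cfg.n_localizer_runs`` runs (12 s on, 7 s ITI).  A block
    activates its class pattern at amplitude ``snr * noise_sd`` in a boxcar
    shifted by the hemodynamic delay, on top of low-frequency drift and
    white noise.
    """
    rng = cfg.rng(_LOCALIZER_STREAM)
    truth = _class_patterns(cfg, rng)
    amplitude = cfg.snr * cfg.noise_sd
    per_run, rem = divmod(cfg.blocks_per_class, cfg.n_localizer_runs)
    n_on = int(round(cfg.block_duration / cfg.tr))

    data_runs, meta_runs, event_rows = [], [], []
    block_id = 0
    for run in range(cfg.n_localizer_runs):
        blocks_this_run = per_run + (1 if run < rem else 0)
        order = _block_order(blocks_this_run, rng)
        onsets = cfg.lead_in + np.arange(len(order)) * (cfg.block_duration + cfg.iti)
        total = onsets[-1] + cfg.block_duration + cfg.iti
        n_vol = int(np.ceil(total / cfg.tr)) + cfg.hemodynamic_delay
        run_data = _noise_and_drift(n_vol, cfg, rng)
        condition = np.full(n_vol, "rest", dtype=object)
        block_col = np.full(n_vol, -1)
        onset_col = np.full(n_vol, -1)
        for cls, onset in zip(order, onsets):
            onset_idx = int(np.floor(onset / cfg.tr))
            start = onset_idx + cfg.hemodynamic_delay
            run_data[start : start + n_on] += amplitude * truth["patterns"][cls]
            stop = min(n_vol, onset_idx + n_on)
            condition[onset_idx:stop] = cls
            block_col[onset_idx:stop] = block_id
            onset_col[onset_idx:stop] = onset_idx
            event_rows.append(
                {
                    "run": run,
                    "block": block_id,
                    "condition": cls,
                    "onset": float(onset),
                    "duration": cfg.block_duration,
                    "onset_index": onset_idx,
                }
            )
            block_id += 1
        data_runs.append(run_data)
        meta_runs.append(
            pd.DataFrame(
                {
                    "run": run,
                    "volume": np.arange(n_vol),
                    "condition": condition,
                    "block": block_col,
                    "onset": onset_col,
                }
            )
        )

    ds = PatternDataset(
        data=np.vstack(data_runs),
        scan_meta=pd.concat(meta_runs, ignore_index=True),
        events=pd.DataFrame(event_rows),
        tr=cfg.tr,
    )
    return ds, truth["signal_voxels"]


def simulate_ac_encoding(
    cfg: SyntheticConfig,
    truth: pd.DataFrame,
    participant_id: Optional[str] = None,
) -> PatternDataset:
    """AC-encoding run whose events carry graded scene reinstatement.

    ``truth`` is the latent table from :func:`simulate_behavior` (one
    participant's rows are selected via ``participant_id``; defaults to the
    first participant).  Each AC event adds the localizer's scene pattern
    at ``onset_index + 3`` volumes with amplitude
    ``gamma * (r - 1) / 2 + jitter``, so reactivation level 1 carries no
    systematic scene signal and level 3 carries the full gain.
    """
    if participant_id is None:
        participant_id = truth["participant_id"].iloc[0]
    rows = truth[truth["participant_id"] == participant_id]
    if rows.empty:
        raise ValidationError(f"participant {participant_id!r} not in truth table")
    # same class patterns as the localizer (same stream and draw order)
    patterns = _class_patterns(cfg, cfg.rng(_LOCALIZER_STREAM))
    scene_pattern = patterns["patterns"]["scene"]
    rng = cfg.rng(_AC_STREAM)

    n_events = len(rows)
    onsets = cfg.lead_in + np.arange(n_events) * cfg.ac_trial_spacing
    n_vol = int(np.ceil((onsets[-1] + cfg.ac_trial_spacing) / cfg.tr)) + 4
    data = _noise_and_drift(n_vol, cfg, rng)
    amp_noise = rng.normal(0.0, cfg.reinstatement_noise, n_events)

    condition = np.full(n_vol, "rest", dtype=object)
    block_col = np.full(n_vol, -1)
    onset_col = np.full(n_vol, -1)
    event_rows = []
    for i, (_, trial) in enumerate(rows.iterrows()):
        onset_idx = int(np.floor(onsets[i] / cfg.tr))
        amplitude = cfg.gamma * (trial["r"] - 1) / 2.0 + amp_noise[i]
        data[onset_idx + 3] += amplitude * cfg.noise_sd * cfg.snr * scene_pattern / 2.0
        stop = min(n_vol, onset_idx + 2)
        condition[onset_idx:stop] = "ac"
        block_col[onset_idx:stop] = i
        onset_col[onset_idx:stop] = onset_idx
        event_rows.append(
            {
                "run": 0,
                "block": i,
                "condition": "ac",
                "onset": float(onsets[i]),
                "duration": 3.0,
                "onset_index": onset_idx,
                "participant_id": participant_id,
                "triad_id": int(trial["triad_id"]),
                "reactivation_level": int(trial["r"]),
            }
        )

    return PatternDataset(
        data=data,
        scan_meta=pd.DataFrame(
            {
                "run": 0,
                "volume": np.arange(n_vol),
                "condition": condition,
                "block": block_col,
                "onset": onset_col,
            }
        ),
        events=pd.DataFrame(event_rows),
        tr=cfg.tr,
    )
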