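"""Scene-vs-face decoding and event-wise reinstatement probabilities.

The decoder is trained on localizer blocks (scenes and faces; object
blocks are ignored): from each 12 s block the volumes 3 TRs and 6 TRs
after onset are taken (the 4th and 7th scans of the block in 1-based
counting), giving 40 training scans for a 10+10 block design.  Pipeline:

1. per-run temporal preprocessing — discrete-cosine high-pass filtering
   (default cutoff 128 s) followed by per-voxel standardization;
2. top-K ANOVA-F feature selection (default K = 250), computed on
   training folds only;
3. L2-regularized linear logistic regression, cross-validated
   leave-one-chunk-out over 20 chunks of 2 scans, each chunk pairing one
   scene and one face scan from different blocks so every test fold is
   class-balanced;
4. chunk-level label-permutation null (default 1000 permutations);
   p = proportion of permuted accuracies >= the observed accuracy;
5. a final model refit on all 40 scans assigns each AC-encoding event
   (volume at onset + 3 TRs) a scene-class probability, read as graded
   evidence of scene reinstatement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression

from .stats import AnovaResult, ConditionTable, condition_summary, rm_anova_2x3
from .types import PatternDataset, ScoredTrial, ValidationError

__all__ = [
    "DecoderSpec",
    "DecodingResult",
    "select_training_scans",
    "temporal_preprocess",
    "select_features",
    "crossvalidate",
    "permutation_test",
    "fit_full_model",
    "decode_events",
    "relate_probabilities_to_conditions",
    "run_decoding_pipeline",
]

logger = logging.getLogger(__name__)

SCENE, FACE = "scene", "face"


@dataclass(frozen=True)
class DecoderSpec:
    """All decoding knobs with the study defaults."""

    k_features: int = 250
    n_chunks: int = 20
    chunk_size: int = 2
    tr_offset: int = 3  # volumes after onset; the second training scan adds 3 more
    n_permutations: int = 1000
    regularization: float = 1.0  # inverse L2 strength (sklearn C)
    highpass_cutoff: float = 128.0  # seconds
    seed: Optional[int] = 0
    plus_one: bool = False  # (k+1)/(n+1) permutation p-value variant
    solver: str = "liblinear"


@dataclass
class DecodingResult:
    cv_accuracy: float
    fold_accuracies: np.ndarray
    permutation_p: Optional[float] = None
    null_accuracies: Optional[np.ndarray] = None
    probabilities: Optional[pd.DataFrame] = None  # per AC event
    anova: Optional[AnovaResult] = None
    n_skipped_events: int = 0

    def __post_init__(self):
        if not 0.0 <= self.cv_accuracy <= 1.0:
            raise ValidationError("cv_accuracy must be in [0, 1]")


def select_training_scans(
    ds: PatternDataset,
    classes: Sequence[str] = (SCENE, FACE),
    tr_offset: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pick the two training volumes per scene/face block.

    Returns (row indices into ``ds.data``, string labels, block ids).  For
    each block of a requested class the volumes at ``onset + tr_offset``
    and ``onset + 2 * tr_offset`` are taken; blocks of other conditions
    (objects, rest) are ignored.
    """
    meta = ds.scan_meta
    run_offsets = {}
    offset = 0
    for run_id in ds.runs:
        run_offsets[run_id] = offset
        offset += int((meta["run"] == run_id).sum())
    run_len = {run_id: int((meta["run"] == run_id).sum()) for run_id in ds.runs}

    indices, labels, blocks = [], [], []
    ev = ds.events
    ev = ev[ev["condition"].isin(classes)]
    for row in ev.itertuples(index=False):
        for k, vol in enumerate((row.onset_index + tr_offset, row.onset_index + 2 * tr_offset)):
            if vol >= run_len[row.run]:
                raise ValidationError(
                    f"block {row.block} ({row.condition}): scan {vol} is beyond the "
                    f"{run_len[row.run]} volumes of run {row.run}"
                )
            indices.append(run_offsets[row.run] + vol)
            labels.append(row.condition)
            blocks.append(row.block)
    return np.asarray(indices, dtype=int), np.asarray(labels), np.asarray(blocks)


def _dct_basis(n: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine drift basis (without the constant term): the
    components with period longer than ``cutoff`` seconds."""
    order = int(np.floor(2.0 * n * tr / cutoff))
    t = np.arange(n)
    basis = [np.cos(np.pi * k * (2 * t + 1) / (2.0 * n)) for k in range(1, order + 1)]
    return np.column_stack(basis) if basis else np.empty((n, 0))


def temporal_preprocess(ds: PatternDataset, highpass_cutoff: float = 128.0) -> PatternDataset:
    """Per-run high-pass filtering then per-voxel standardization.

    Each run is projected off a discrete-cosine drift basis (periods longer
    than ``highpass_cutoff`` seconds, constant included), then every voxel
    is standardized to mean 0, SD 1 within the run.  Voxels that are
    constant (zero variance) in any run are zeroed everywhere and flagged.
    """
    out = ds.data.copy()
    flagged = ds.flagged_voxels.copy()
    for run_id in ds.runs:
        rows = ds.run_slice(run_id)
        n = int(rows.sum())
        if n < 3:
            raise ValidationError(f"run {run_id} has only {n} volumes; need >= 3")
        block = out[rows]
        basis = np.column_stack([np.ones(n), _dct_basis(n, ds.tr, highpass_cutoff)])
        coef, *_ = np.linalg.lstsq(basis, block, rcond=None)
        block = block - basis @ coef
        sd = block.std(axis=0, ddof=0)
        constant = sd <= 1e-12
        flagged |= constant
        sd_safe = np.where(constant, 1.0, sd)
        block = block / sd_safe
        block[:, constant] = 0.0
        out[rows] = block
    out[:, flagged] = 0.0
    return replace(
        ds,
        data=out,
        scan_meta=ds.scan_meta,
        events=ds.events,
        flagged_voxels=flagged,
    )


def select_features(train: np.ndarray, labels: np.ndarray, k: int = 250) -> np.ndarray:
    """Indices of the K voxels with the largest between-class ANOVA F on
    the training scans; ties break towards the lower voxel index."""
    if k > train.shape[1]:
        raise ValidationError(f"k = {k} exceeds {train.shape[1]} voxels")
    f_stat, _ = f_classif(train, labels)
    f_stat = np.nan_to_num(f_stat, nan=0.0)
    order = np.argsort(-f_stat, kind="stable")  # stable: equal F -> ascending index
    return np.sort(order[:k])


def _make_chunks(
    labels: np.ndarray, blocks: np.ndarray, n_chunks: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign scans to chunks: each chunk pairs one scene and one face scan
    from different blocks (guaranteed since the classes' blocks are
    disjoint), deterministically from the rng."""
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 classes, got {list(classes)}")
    idx_a = np.flatnonzero(labels == classes[0])
    idx_b = np.flatnonzero(labels == classes[1])
    if len(idx_a) != len(idx_b):
        raise ValidationError(
            f"class imbalance: {len(idx_a)} vs {len(idx_b)} training scans"
        )
    if len(idx_a) != n_chunks:
        raise ValidationError(
            f"{n_chunks} chunks of one scan per class need {n_chunks} scans per "
            f"class, got {len(idx_a)}"
        )
    chunk = np.empty(labels.size, dtype=int)
    chunk[idx_a[rng.permutation(len(idx_a))]] = np.arange(n_chunks)
    chunk[idx_b[rng.permutation(len(idx_b))]] = np.arange(n_chunks)
    return chunk


def _fit_clf(x: np.ndarray, y: np.ndarray, spec: DecoderSpec) -> LogisticRegression:
    # L2 penalty (sklearn default) at inverse strength C; deterministic solver
    clf = LogisticRegression(C=spec.regularization, solver=spec.solver, max_iter=1000)
    clf.fit(x, y)
    return clf


def _cv_accuracy(
    data: np.ndarray,
    y: np.ndarray,
    chunk: np.ndarray,
    spec: DecoderSpec,
) -> tuple[float, np.ndarray]:
    folds = np.unique(chunk)
    accs = np.empty(folds.size)
    for i, fold in enumerate(folds):
        test = chunk == fold
        train = ~test
        feats = select_features(data[train], y[train], spec.k_features)
        clf = _fit_clf(data[np.ix_(train, feats)], y[train], spec)
        accs[i] = float(np.mean(clf.predict(data[np.ix_(test, feats)]) == y[test]))
    return float(accs.mean()), accs


def crossvalidate(
    data: np.ndarray,
    labels: np.ndarray,
    blocks: np.ndarray,
    spec: DecoderSpec = DecoderSpec(),
    rng: Optional[np.random.Generator] = None,
) -> tuple[DecodingResult, np.ndarray]:
    """Leave-one-chunk-out CV accuracy of the scene/face decoder.

    ``data`` is the preprocessed (scans x voxels) training matrix with one
    row per selected localizer scan.  Feature selection and the logistic
    fit are redone inside every fold on the training scans only.  Returns
    the result and the chunk assignment (reused by the permutation test).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    y = np.asarray(labels)
    chunk = _make_chunks(y, np.asarray(blocks), spec.n_chunks, rng)
    acc, fold_accs = _cv_accuracy(data, y, chunk, spec)
    return DecodingResult(cv_accuracy=acc, fold_accuracies=fold_accs), chunk


def permutation_test(
    data: np.ndarray,
    labels: np.ndarray,
    chunk: np.ndarray,
    observed_accuracy: float,
    spec: DecoderSpec = DecoderSpec(),
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, np.ndarray]:
    """Chunk-level label-permutation null for the CV accuracy.

    Each permutation re-assigns the class labels within every chunk (a
    seeded coin flip swaps the chunk's scene/face labels), re-runs the full
    cross-validation including feature selection, and records the accuracy.
    p = #(null >= observed) / n; with ``spec.plus_one`` the
    (k + 1) / (n + 1) variant is used instead.
    """
    if spec.n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    if rng is None:
        rng = np.random.default_rng(None if spec.seed is None else spec.seed + 1)
    y = np.asarray(labels)
    null = np.empty(spec.n_permutations)
    chunks = np.unique(chunk)
    for b in range(spec.n_permutations):
        permuted = y.copy()
        flips = rng.random(chunks.size) < 0.5
        for c, flip in zip(chunks, flips):
            if flip:
                members = np.flatnonzero(chunk == c)
                permuted[members] = permuted[members][::-1]
        null[b], _ = _cv_accuracy(data, permuted, chunk, spec)
    k = int(np.sum(null >= observed_accuracy))
    if spec.plus_one:
        p = (k + 1) / (spec.n_permutations + 1)
    else:
        p = k / spec.n_permutations
    return float(p), null


def fit_full_model(
    data: np.ndarray, labels: np.ndarray, spec: DecoderSpec = DecoderSpec()
) -> tuple[LogisticRegression, np.ndarray]:
    """Refit feature selection + classifier on all training scans (the
    model applied to AC-encoding events)."""
    y = np.asarray(labels)
    feats = select_features(data, y, spec.k_features)
    clf = _fit_clf(data[:, feats], y, spec)
    return clf, feats


def decode_events(
    model: LogisticRegression,
    features: np.ndarray,
    ac: PatternDataset,
    tr_offset: int = 3,
    positive_class: str = SCENE,
) -> tuple[pd.DataFrame, int]:
    """Scene-class probability for each AC-encoding event.

    For every event the volume at ``onset_index + tr_offset`` is taken,
    restricted to the selected voxels, and scored with the trained model.
    Events whose target volume falls outside the run are skipped with a
    logged warning; the skip count is returned.
    """
    meta = ac.scan_meta
    run_offsets, offset = {}, 0
    for run_id in ac.runs:
        run_offsets[run_id] = offset
        offset += int((meta["run"] == run_id).sum())
    run_len = {run_id: int((meta["run"] == run_id).sum()) for run_id in ac.runs}
    pos_col = int(np.flatnonzero(model.classes_ == positive_class)[0])

    rows, skipped = [], 0
    for row in ac.events.itertuples(index=False):
        vol = row.onset_index + tr_offset
        if vol >= run_len[row.run]:
            skipped += 1
            continue
        x = ac.data[run_offsets[row.run] + vol, features][None, :]
        prob = float(model.predict_proba(x)[0, pos_col])
        record = {"run": row.run, "event": row.block, "probability": prob}
        for extra in ("participant_id", "triad_id", "reactivation_level"):
            if hasattr(row, extra):
                record[extra] = getattr(row, extra)
        rows.append(record)
    if skipped:
        logger.warning("decode_events: skipped %d event(s) beyond run end", skipped)
    return pd.DataFrame(rows), skipped


def relate_probabilities_to_conditions(
    probabilities: Sequence[float],
    scored: Sequence[ScoredTrial],
) -> tuple[AnovaResult, ConditionTable]:
    """2 x 3 RM-ANOVA of decoded scene probabilities over the behavioral
    (congruency x reactivation) cells; ``probabilities`` aligns with
    ``scored`` trial-by-trial."""
    table = condition_summary(scored, value="probability", values=list(probabilities))
    return rm_anova_2x3(table), table


def run_decoding_pipeline(
    localizer: PatternDataset,
    ac: Optional[PatternDataset] = None,
    spec: DecoderSpec = DecoderSpec(),
    run_permutations: bool = True,
) -> DecodingResult:
    """Full pipeline: preprocess, CV, permutation null, AC event decoding."""
    loc = temporal_preprocess(localizer, spec.highpass_cutoff)
    idx, labels, blocks = select_training_scans(loc, tr_offset=spec.tr_offset)
    train = loc.data[idx]
    result, chunk = crossvalidate(train, labels, blocks, spec)
    if run_permutations:
        result.permutation_p, result.null_accuracies = permutation_test(
            train, labels, chunk, result.cv_accuracy, spec
        )
    if ac is not None:
        model, feats = fit_full_model(train, labels, spec)
        ac_pre = temporal_preprocess(ac, spec.highpass_cutoff)
        result.probabilities, result.n_skipped_events = decode_events(
            model, feats, ac_pre, tr_offset=spec.tr_offset
        )
    return result
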