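"""Readers and writers for behavioral tables, NIfTI pattern data and results.

Behavioral tables are delimited text (TSV by default) with one row per
trial, BIDS-events flavoured.  Fixed schemas:

``encoding``
    participant_id, triad_id, designed_congruency, reactivation_response,
    reaction_time
``test``
    participant_id, object_id, is_lure, triad_id, item_confidence,
    recall_rater1, recall_rater2, assoc_confidence, assoc_correct_side
``ratings``
    participant_id, triad_id, rating

Missing responses are empty cells and survive a write/read round-trip as
missing — they are never collapsed onto 0.

Pattern data are NIfTI-1: a 4-D data image per run plus a 3-D binary mask
on the same grid, an events TSV (onset, duration, trial_type, block, run,
plus free extra columns) and a JSON sidecar carrying the repetition time.
Onsets in seconds map to 0-based volume indices by ``floor(onset / tr)``
(the paper-style 1-based "4th scan" of a block is ``onset_index + 3``
here).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .types import (
    CongruencyRating,
    EncodingTrial,
    PatternDataset,
    ScoredTrial,
    TestTrial,
    ValidationError,
)

__all__ = [
    "SchemaError",
    "ENCODING_COLUMNS",
    "TEST_COLUMNS",
    "RATING_COLUMNS",
    "SCORED_COLUMNS",
    "read_behavior_tables",
    "read_encoding_table",
    "read_test_table",
    "read_rating_table",
    "read_scored_table",
    "read_pattern_dataset",
    "write_table",
    "write_results",
    "write_pattern_dataset",
    "records_to_frame",
]


class SchemaError(ValueError):
    """A table is missing required columns."""


ENCODING_COLUMNS = (
    "participant_id",
    "triad_id",
    "designed_congruency",
    "reactivation_response",
    "reaction_time",
)
TEST_COLUMNS = (
    "participant_id",
    "object_id",
    "is_lure",
    "triad_id",
    "item_confidence",
    "recall_rater1",
    "recall_rater2",
    "assoc_confidence",
    "assoc_correct_side",
)
RATING_COLUMNS = ("participant_id", "triad_id", "rating")
SCORED_COLUMNS = (
    "participant_id",
    "triad_id",
    "item_points",
    "recall_points",
    "assoc_points",
    "memory_score",
    "congruency_bin",
    "reactivation_level",
)


def _read_table(path, required: Sequence[str], sep: str = "\t") -> pd.DataFrame:
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return frame


def _opt_int(value, name: str, row: int):
    if value is None or (isinstance(value, float) and np.isnan(value)) or pd.isna(value):
        return None
    try:
        as_float = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: {name} is not numeric: {value!r}") from None
    if as_float != int(as_float):
        raise ValidationError(f"row {row}: {name} must be an integer, got {value!r}")
    return int(as_float)


def _opt_float(value, name: str, row: int):
    if value is None or pd.isna(value):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: {name} is not numeric: {value!r}") from None


def _opt_str(value):
    if value is None or pd.isna(value) or value == "":
        return None
    return str(value)


def _parse_bool(value, name: str, row: int) -> bool:
    text = str(value).strip().lower()
    if text in ("1", "true", "yes"):
        return True
    if text in ("0", "false", "no"):
        return False
    raise ValidationError(f"row {row}: {name} must be boolean-like, got {value!r}")


def read_encoding_table(path, sep: str = "\t") -> list[EncodingTrial]:
    frame = _read_table(path, ENCODING_COLUMNS, sep)
    trials = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            trials.append(
                EncodingTrial(
                    participant_id=str(row.participant_id),
                    triad_id=_opt_int(row.triad_id, "triad_id", i),
                    designed_congruency=str(row.designed_congruency),
                    reactivation_response=_opt_int(
                        row.reactivation_response, "reactivation_response", i
                    ),
                    reaction_time=_opt_float(row.reaction_time, "reaction_time", i),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from None
    _check_unique_triads(trials, path)
    return trials


def _check_unique_triads(trials: Iterable, path) -> None:
    seen = set()
    for t in trials:
        key = (t.participant_id, t.triad_id)
        if key in seen:
            raise ValidationError(f"{path}: duplicate triad {key}")
        seen.add(key)


def read_test_table(path, sep: str = "\t") -> list[TestTrial]:
    frame = _read_table(path, TEST_COLUMNS, sep)
    trials = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            trials.append(
                TestTrial(
                    participant_id=str(row.participant_id),
                    object_id=str(row.object_id),
                    is_lure=_parse_bool(row.is_lure, "is_lure", i),
                    triad_id=_opt_int(row.triad_id, "triad_id", i),
                    item_confidence=_opt_int(row.item_confidence, "item_confidence", i),
                    recall_rater1=_opt_float(row.recall_rater1, "recall_rater1", i),
                    recall_rater2=_opt_float(row.recall_rater2, "recall_rater2", i),
                    assoc_confidence=_opt_int(row.assoc_confidence, "assoc_confidence", i),
                    assoc_correct_side=_opt_str(row.assoc_correct_side),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from None
    return trials


def read_rating_table(path, sep: str = "\t") -> list[CongruencyRating]:
    frame = _read_table(path, RATING_COLUMNS, sep)
    ratings = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            ratings.append(
                CongruencyRating(
                    participant_id=str(row.participant_id),
                    triad_id=_opt_int(row.triad_id, "triad_id", i),
                    rating=_opt_int(row.rating, "rating", i),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from None
    seen = set()
    for r in ratings:
        key = (r.participant_id, r.triad_id)
        if key in seen:
            raise ValidationError(f"{path}: duplicate rating for {key}")
        seen.add(key)
    return ratings


def read_scored_table(path, sep: str = "\t") -> list[ScoredTrial]:
    frame = _read_table(path, SCORED_COLUMNS, sep)
    scored = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            scored.append(
                ScoredTrial(
                    participant_id=str(row.participant_id),
                    triad_id=_opt_int(row.triad_id, "triad_id", i),
                    item_points=_opt_int(row.item_points, "item_points", i),
                    recall_points=_opt_float(row.recall_points, "recall_points", i),
                    assoc_points=_opt_int(row.assoc_points, "assoc_points", i),
                    memory_score=_opt_float(row.memory_score, "memory_score", i),
                    congruency_bin=_opt_str(row.congruency_bin),
                    reactivation_level=_opt_int(row.reactivation_level, "reactivation_level", i),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from None
    return scored


def read_behavior_tables(
    encoding_path=None, test_path=None, ratings_path=None, sep: str = "\t"
) -> tuple[list[EncodingTrial], list[TestTrial], list[CongruencyRating]]:
    """Read any subset of the three behavioral tables; absent paths give []."""
    encoding = read_encoding_table(encoding_path, sep) if encoding_path else []
    test = read_test_table(test_path, sep) if test_path else []
    ratings = read_rating_table(ratings_path, sep) if ratings_path else []
    return encoding, test, ratings


# ---------------------------------------------------------------------------
# writing


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Dataclass records -> DataFrame with one column per field."""
    if not records:
        return pd.DataFrame()
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def write_table(records_or_frame, path, columns: Optional[Sequence[str]] = None,
                sep: str = "\t") -> Path:
    """Write records (or a frame) as delimited text; empty cells mark missing."""
    path = Path(path)
    if isinstance(records_or_frame, pd.DataFrame):
        frame = records_or_frame
    else:
        frame = records_to_frame(list(records_or_frame))
    if frame.empty and columns is not None:
        frame = pd.DataFrame(columns=list(columns))
    elif columns is not None:
        frame = frame.reindex(columns=list(columns))
    path.parent.mkdir(parents=True, exist_ok=True)
    out = frame.copy()
    if "is_lure" in out.columns and len(out):
        out["is_lure"] = out["is_lure"].astype(int)
    # integers with missing values: write without trailing ".0"
    for col in out.columns:
        if out[col].dtype == object or out[col].dtype.kind not in "if":
            continue
        values = out[col].dropna()
        if len(values) and np.all(np.mod(values, 1) == 0) and col not in (
            "recall_rater1", "recall_rater2", "recall_points", "memory_score",
            "reaction_time", "rating_mean",
        ):
            out[col] = out[col].astype("Int64")
    out.to_csv(path, sep=sep, index=False, float_format="%.12g")
    return path


def write_results(records, path, sep: str = "\t") -> Path:
    """Write a stage output: tables -> TSV, structured summaries -> JSON.

    Lists of dataclass records and DataFrames become delimited text;
    dictionaries (e.g. ANOVA or decoding summaries) become pretty-printed
    JSON that reloads losslessly with :func:`json.load`.
    """
    path = Path(path)
    if isinstance(records, dict):
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(records, fh, indent=2, default=_json_default)
            fh.write("\n")
        return path
    if dataclasses.is_dataclass(records) and not isinstance(records, type):
        return write_results(dataclasses.asdict(records), path)
    return write_table(records, path, sep=sep)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# NIfTI pattern data


def read_pattern_dataset(
    nifti_4d: Union[str, Path, Sequence[Union[str, Path]]],
    mask: Union[str, Path],
    events: Union[str, Path, pd.DataFrame],
    tr: Optional[float] = None,
    sidecar: Optional[Union[str, Path]] = None,
) -> PatternDataset:
    """Load 4-D run image(s) + binary mask + events into a PatternDataset.

    ``nifti_4d`` may be a single path or a sequence of per-run paths; runs
    are identified by the ``run`` column of the events table (defaulting to
    run 0...n in file order).  ``tr`` may instead come from a JSON sidecar
    with a ``RepetitionTime`` field.
    """
    if tr is None:
        if sidecar is None:
            raise ValidationError("tr not given and no JSON sidecar provided")
        with open(sidecar) as fh:
            tr = float(json.load(fh)["RepetitionTime"])
    if tr <= 0:
        raise ValidationError(f"tr must be positive, got {tr}")

    paths = [nifti_4d] if isinstance(nifti_4d, (str, Path)) else list(nifti_4d)
    mask_img = nib.load(str(mask))
    mask_data = np.asarray(mask_img.dataobj) > 0
    n_vox = int(mask_data.sum())
    if n_vox == 0:
        raise ValidationError("mask selects no voxels")
    voxel_index = np.array(np.nonzero(mask_data)).T

    if isinstance(events, pd.DataFrame):
        ev = events.copy()
    else:
        ev = pd.read_csv(events, sep="\t")
    for col in ("onset", "duration", "trial_type"):
        if col not in ev.columns:
            raise SchemaError(f"events table missing column {col!r}")
    if "run" not in ev.columns:
        ev["run"] = 0
    if "block" not in ev.columns:
        ev["block"] = np.arange(len(ev))
    ev["onset_index"] = np.floor(ev["onset"] / tr).astype(int)
    ev = ev.rename(columns={"trial_type": "condition"})

    blocks_data = []
    meta_rows = []
    run_ids = sorted(pd.unique(ev["run"])) if len(ev) else list(range(len(paths)))
    if len(run_ids) != len(paths):
        run_ids = list(range(len(paths)))
    for run_id, path in zip(run_ids, paths):
        img = nib.load(str(path))
        if img.shape[:3] != mask_data.shape:
            raise ValidationError(
                f"{path}: grid {img.shape[:3]} does not match mask grid {mask_data.shape}"
            )
        vol = np.asarray(img.dataobj, dtype=float)
        n_t = vol.shape[3] if vol.ndim == 4 else 1
        matrix = vol[mask_data].T  # (time, voxels)
        blocks_data.append(matrix)
        run_ev = ev[ev["run"] == run_id]
        if len(run_ev) and run_ev["onset_index"].max() >= n_t:
            bad = run_ev.loc[run_ev["onset_index"].idxmax()]
            raise ValidationError(
                f"event block {bad['block']} onset {bad['onset']} s is beyond the "
                f"{n_t} volumes of run {run_id}"
            )
        condition = np.full(n_t, "rest", dtype=object)
        block = np.full(n_t, -1)
        onset_idx = np.full(n_t, -1)
        for row in run_ev.itertuples(index=False):
            start = int(row.onset_index)
            stop = min(n_t, start + max(1, int(np.ceil(row.duration / tr))))
            condition[start:stop] = row.condition
            block[start:stop] = row.block
            onset_idx[start:stop] = start
        meta_rows.append(
            pd.DataFrame(
                {
                    "run": run_id,
                    "volume": np.arange(n_t),
                    "condition": condition,
                    "block": block,
                    "onset": onset_idx,
                }
            )
        )

    data = np.vstack(blocks_data)
    scan_meta = pd.concat(meta_rows, ignore_index=True)
    return PatternDataset(
        data=data,
        scan_meta=scan_meta,
        events=ev.reset_index(drop=True),
        tr=float(tr),
        voxel_index=voxel_index,
    )


def write_pattern_dataset(
    ds: PatternDataset,
    out_dir: Union[str, Path],
    prefix: str,
    grid: Optional[tuple[int, int, int]] = None,
) -> dict:
    """Write a PatternDataset as per-run 4-D NIfTI + mask + events + sidecar.

    Voxels are embedded into a rectangular grid (default: a near-cubic grid
    just large enough); the mask marks the occupied cells.  Returns a dict
    of written paths keyed by role.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_vox = ds.n_voxels
    if grid is None:
        side = int(np.ceil(n_vox ** (1 / 3)))
        nz = int(np.ceil(n_vox / side**2))
        grid = (side, side, nz)
    if int(np.prod(grid)) < n_vox:
        raise ValidationError(f"grid {grid} too small for {n_vox} voxels")
    mask = np.zeros(grid, dtype=np.uint8)
    flat = np.zeros(int(np.prod(grid)), dtype=np.uint8)
    flat[:n_vox] = 1
    mask = flat.reshape(grid)
    affine = np.eye(4)
    paths = {}
    mask_path = out_dir / f"{prefix}_mask.nii"
    nib.save(nib.Nifti1Image(mask, affine), str(mask_path))
    paths["mask"] = mask_path
    coords = np.array(np.nonzero(mask)).T
    run_paths = []
    for run_id in ds.runs:
        rows = ds.run_slice(run_id)
        matrix = ds.data[rows]  # (time, vox)
        vol = np.zeros(grid + (matrix.shape[0],), dtype=np.float32)
        vol[coords[:, 0], coords[:, 1], coords[:, 2], :] = matrix.T
        run_path = out_dir / f"{prefix}_run-{run_id}.nii"
        nib.save(nib.Nifti1Image(vol, affine), str(run_path))
        run_paths.append(run_path)
    paths["runs"] = run_paths
    ev = ds.events.rename(columns={"condition": "trial_type"})
    ev_path = out_dir / f"{prefix}_events.tsv"
    ev.to_csv(ev_path, sep="\t", index=False)
    paths["events"] = ev_path
    sidecar_path = out_dir / f"{prefix}.json"
    with open(sidecar_path, "w") as fh:
        json.dump({"RepetitionTime": ds.tr}, fh)
        fh.write("\n")
    paths["sidecar"] = sidecar_path
    return paths
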