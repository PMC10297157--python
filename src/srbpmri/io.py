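"""Reading and writing of MRI volumes, cohort tables and metric files.

Volumes are MetaImage (``.mha``) or NIfTI (``.nii``/``.nii.gz``) files read
through SimpleITK.  Arrays are handled in ``(slices, rows, cols)`` order,
matching the convention that the axial slice index is the leading axis.
World coordinates follow ``origin + index * spacing`` with 0-based voxel
indices; volumes with a non-identity direction matrix are rejected rather
than silently resampled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk

logger = logging.getLogger(__name__)

CHANNELS = ("ADC", "HBV", "T2")

TECHNIQUES = ("SysBx", "MRBx", "SysBx+MRBx", "RP")

COHORT_COLUMNS = (
    "patient_id",
    "isup",
    "psa_ng_ml",
    "age_years",
    "prostate_vol_cc",
    "scanner",
    "technique",
)

_VALID_SUFFIXES = (".mha", ".nii", ".nii.gz")


@dataclass
class SequenceImage:
    """One MRI channel volume together with its geometry metadata.

    Parameters
    ----------
    array
        Voxel intensities, shape ``(slices, rows, cols)``.
    spacing
        Physical voxel size in mm per axis, ordered like the array axes.
    origin
        World coordinate (mm) of voxel ``(0, 0, 0)``, ordered like the
        array axes.
    channel
        Sequence label, one of ``ADC``, ``HBV`` or ``T2``.
    """

    array: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    channel: str

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=float)
        if self.array.ndim != 3:
            raise ValueError(f"non-3D volume: got {self.array.ndim} dimensions")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.array)):
            raise ValueError("volume contains non-finite values")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.array.shape

    def slice_z(self, k: int) -> float:
        """World z-position (mm) of axial slice ``k``."""
        return self.origin[0] + k * self.spacing[0]


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VALID_SUFFIXES):
        raise ValueError(
            f"unsupported extension for {path.name!r}; expected one of {_VALID_SUFFIXES}"
        )


def read_sequence(path: str | Path, channel: str) -> SequenceImage:
    """Read one channel volume; geometry comes from the image header.

    SimpleITK reports spacing/origin in ``(x, y, z)`` order while the array
    comes back ``(z, y, x)``; both are normalised here to the array order
    ``(slices, rows, cols)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_suffix(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"non-3D volume: {path.name} has dimension {img.GetDimension()}")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError(
            f"{path.name}: non-identity direction matrix is not supported"
        )
    arr = sitk.GetArrayFromImage(img).astype(float)
    spacing = img.GetSpacing()[::-1]
    origin = img.GetOrigin()[::-1]
    return SequenceImage(arr, spacing, origin, channel)


def write_sequence(seq: SequenceImage, path: str | Path) -> None:
    """Write a channel volume with its geometry to ``.mha`` or NIfTI."""
    path = Path(path)
    _check_suffix(path)
    img = sitk.GetImageFromArray(seq.array)
    img.SetSpacing(tuple(seq.spacing[::-1]))
    img.SetOrigin(tuple(seq.origin[::-1]))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))


def read_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float], tuple[float, float, float]]:
    """Read a label mask volume; returns (labels, spacing, origin).

    Labels: 0 background, 1 prostate, 2 tumor ROI.
    """
    path = Path(path)
    _check_suffix(path)
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).astype(np.uint8)
    return arr, img.GetSpacing()[::-1], img.GetOrigin()[::-1]


def write_mask(
    labels: np.ndarray,
    spacing: Sequence[float],
    origin: Sequence[float],
    path: str | Path,
) -> None:
    img = sitk.GetImageFromArray(np.asarray(labels, dtype=np.uint8))
    img.SetSpacing(tuple(float(s) for s in spacing[::-1]))
    img.SetOrigin(tuple(float(o) for o in origin[::-1]))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the cohort CSV.

    Required columns: ``patient_id, isup, psa_ng_ml, age_years,
    prostate_vol_cc, scanner, technique``.  Rows with a missing ISUP grade
    are dropped with a warning; an out-of-range grade or a duplicated
    patient id is an error.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    n_na = int(df["isup"].isna().sum())
    if n_na:
        logger.warning("dropping %d rows with missing ISUP grade", n_na)
        df = df.dropna(subset=["isup"])
    df = df.copy()
    df["isup"] = df["isup"].astype(int)
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient ids: {dupes}")
    bad = df[~df["isup"].between(0, 5)]
    if len(bad):
        raise ValueError(f"ISUP grade out of range 0..5 for ids {bad['patient_id'].tolist()}")
    for col in ("psa_ng_ml", "age_years", "prostate_vol_cc"):
        if (df[col] <= 0).any():
            raise ValueError(f"column {col} must be positive")
    return df.reset_index(drop=True)


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, columns=list(COHORT_COLUMNS))


def write_metrics(
    scores: pd.DataFrame,
    summaries: Iterable[Mapping],
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write per-patient scores (long CSV) and the evaluation summary (JSON).

    ``scores`` needs columns ``patient_id, variant, score``; ``summaries``
    is an iterable of mappings (one per variant) that are serialised as-is.
    Returns the two file paths.
    """
    if scores is None or len(scores) == 0:
        raise ValueError("empty results")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    required = ["patient_id", "variant", "score"]
    missing = [c for c in required if c not in scores.columns]
    if missing:
        raise ValueError(f"scores table missing columns: {missing}")
    scores_path = out_dir / "scores.csv"
    scores[required].to_csv(scores_path, index=False)
    summary_path = out_dir / "evaluation.json"
    payload = list(summaries)
    if not payload:
        raise ValueError("empty results")
    with open(summary_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return scores_path, summary_path


def read_metrics(out_dir: str | Path) -> tuple[pd.DataFrame, list[dict]]:
    """Round-trip companion of :func:`write_metrics`."""
    out_dir = Path(out_dir)
    scores = pd.read_csv(out_dir / "scores.csv")
    with open(out_dir / "evaluation.json") as fh:
        summaries = json.load(fh)
    return scores, summaries
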