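"""Volumetric morphometry on multi-label 3D segmentations.

Structures (muscles, bones) are stored as one integer label each in a 3D
array with known voxel spacing. Volume is voxel count × voxel volume;
bone length is the extent of the label's voxel cloud along its first
principal axis — the standard definition of a long-bone length from a
segmentation. Relative muscle volume divides each muscle's volume by the
summed volume of the 10 muscle groups (bones never enter the
denominator).

Units: array spacing is mm per axis; volumes are reported in cm³ and
lengths in cm. Conversions happen here, at the measurement boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import VOLUME_COLUMNS, total_volume, tsurae_volume, volume_col
from .muscles import AGE_BANDS, MUSCLES, SEXES, band_label, find_band, validate_bands

MM3_PER_CM3 = 1000.0
MM_PER_CM = 10.0


class UnknownLabelError(KeyError):
    """Label id not present in the label dictionary."""


class DegenerateGeometryError(ValueError):
    """Too few voxels to define the requested geometric quantity."""


@dataclass
class LabelVolume:
    """A 3D integer label image with physical voxel spacing.

    Attributes
    ----------
    data
        3D integer array; 0 is background and is never in ``labels``.
    spacing
        Voxel edge lengths in mm per axis.
    labels
        Maps label id -> (structure code, kind), kind in {"muscle", "bone"}.
    ground_truth
        Optional analytic truth per label (e.g. from a phantom):
        {label id: {"volume_cm3": ..., "length_cm": ...}}.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    labels: dict[int, tuple[str, str]]
    ground_truth: dict[int, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be a 3D integer array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be three positive lengths (mm)")
        if 0 in self.labels:
            raise ValueError("label 0 is reserved for background")
        present = set(np.unique(self.data)) - {0}
        unknown = present - set(self.labels)
        if unknown:
            raise ValueError(f"array contains labels missing from dictionary: {sorted(unknown)}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        """Diagonal index→mm affine carrying the voxel spacing."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        return aff


def label_volume(lv: LabelVolume, label: int) -> float:
    """Volume of one label in cm³ (voxel count × voxel volume).

    A label that is in the dictionary but absent from the array has
    volume 0; a label missing from the dictionary raises
    :class:`UnknownLabelError`.
    """
    if label not in lv.labels:
        raise UnknownLabelError(label)
    count = int(np.count_nonzero(lv.data == label))
    return count * lv.voxel_volume_mm3 / MM3_PER_CM3


def bone_length(lv: LabelVolume, label: int) -> float:
    """Extent (cm) of a label along its first principal axis.

    Voxel centers of the label are mapped to physical mm coordinates,
    centred, and projected on the leading eigenvector of their
    covariance; the length is max − min of the projections.
    """
    if label not in lv.labels:
        raise UnknownLabelError(label)
    idx = np.argwhere(lv.data == label)
    if len(idx) < 2:
        raise DegenerateGeometryError(
            f"label {label} has {len(idx)} voxel(s); need >= 2 for a length"
        )
    coords = (idx.astype(float) + 0.5) * np.asarray(lv.spacing)  # voxel centers
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / (len(centred) - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, -1]  # leading eigenvector
    proj = centred @ axis
    return float(proj.max() - proj.min()) / MM_PER_CM


def measure_participant(lv: LabelVolume, participant: str | None = None) -> dict[str, float]:
    """All structure volumes plus bone lengths for one label image.

    Returns a record with ``V_<code>`` (cm³) for every muscle label and
    ``<code>_length`` (cm) for every bone label.
    """
    rec: dict[str, float] = {}
    if participant is not None:
        rec["participant"] = participant  # type: ignore[assignment]
    for label, (code, kind) in sorted(lv.labels.items()):
        if kind == "muscle":
            rec[volume_col(code)] = label_volume(lv, label)
        elif kind == "bone":
            rec[f"{code.lower()}_length"] = bone_length(lv, label)
        else:
            raise ValueError(f"unknown structure kind {kind!r} for label {label}")
    return rec


def relative_volumes(record: dict[str, float] | pd.Series) -> dict[str, float]:
    """Relative volume r_m = V_m / Σ V_k over the 10 muscle groups.

    Requires all 10 muscle volumes present and strictly positive; the
    result sums to 1 and is invariant to a common rescaling of the
    volumes.
    """
    vols = {}
    for m in MUSCLES:
        v = record.get(volume_col(m)) if isinstance(record, dict) else record.get(volume_col(m))
        if v is None or not np.isfinite(v) or v <= 0:
            raise ValueError(f"incomplete record: muscle {m} volume missing or non-positive")
        vols[m] = float(v)
    total = sum(vols.values())
    return {f"r_{m}": v / total for m, v in vols.items()}


def summarize_groups(
    cohort: pd.DataFrame,
    bands: tuple[tuple[float, float], ...] = AGE_BANDS,
) -> pd.DataFrame:
    """Group summary (mean, SD, min, max, n) per sex × age band.

    Mirrors the layout of a normative cohort table: covariates first,
    then the 10 muscle volumes, then derived TSURAE and TOTAL. Rows not
    flagged ``included`` are omitted; included rows whose age falls in
    no band are reported under an explicit ``"unbinned"`` bucket rather
    than silently dropped. SD uses the n−1 denominator and is NaN with
    a ``sd_undefined`` flag when n < 2.
    """
    validate_bands(bands)
    inc = cohort[cohort["included"].astype(bool)].copy()
    inc["TSURAE"] = tsurae_volume(inc)
    inc["TOTAL"] = total_volume(inc)
    variables = [
        "age", "body_mass", "height", "fibula_length", "tibia_length",
        *VOLUME_COLUMNS, "TSURAE", "TOTAL",
    ]
    rows = []
    for sex in SEXES:
        sub_sex = inc[inc["sex"] == sex]
        buckets = [(band_label(lo, hi), (lo, hi)) for lo, hi in sorted(bands)]
        buckets.append(("unbinned", None))
        for name, band in buckets:
            if band is None:
                in_band = sub_sex["age"].map(lambda a: find_band(a, bands) is None)
            else:
                lo, hi = band
                in_band = (sub_sex["age"] >= lo) & (sub_sex["age"] < hi)
            grp = sub_sex[in_band]
            n = len(grp)
            if n == 0 and band is None:
                continue  # only report the unbinned bucket when occupied
            for var in variables:
                x = grp[var].to_numpy(float)
                x = x[np.isfinite(x)]
                k = len(x)
                rows.append(
                    {
                        "sex": sex,
                        "band": name,
                        "variable": var,
                        "n": k,
                        "mean": float(np.mean(x)) if k else np.nan,
                        "sd": float(np.std(x, ddof=1)) if k >= 2 else np.nan,
                        "sd_undefined": k < 2,
                        "min": float(np.min(x)) if k else np.nan,
                        "max": float(np.max(x)) if k else np.nan,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O: NIfTI volume + JSON sidecar
# ---------------------------------------------------------------------------

def write_label_volume(lv: LabelVolume, path: str | Path) -> None:
    """Write as uncompressed NIfTI plus a ``.json`` sidecar.

    The sidecar records the label dictionary and, for phantoms, the
    analytic ground truth.
    """
    path = Path(path)
    img = nib.Nifti1Image(lv.data.astype(np.int16), lv.affine)
    img.header.set_zooms(lv.spacing)
    nib.save(img, str(path))
    sidecar = {
        "labels": {str(k): {"code": code, "kind": kind} for k, (code, kind) in lv.labels.items()},
        "ground_truth": {str(k): v for k, v in lv.ground_truth.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a NIfTI label image and its JSON sidecar."""
    path = Path(path)
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    meta = json.loads(path.with_suffix(".json").read_text())
    labels = {int(k): (v["code"], v["kind"]) for k, v in meta["labels"].items()}
    gt = {int(k): v for k, v in meta.get("ground_truth", {}).items()}
    data = np.asarray(img.dataobj).astype(np.int32)
    return LabelVolume(data=data, spacing=spacing, labels=labels, ground_truth=gt)
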