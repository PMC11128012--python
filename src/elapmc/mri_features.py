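"""Tumor-descriptor features from labeled MRI segmentation volumes.

A BRATS-style segmentation labels every voxel as background or one of four
tumor descriptor regions: necrosis, edema, non-enhancing tumor, and
contrast-enhancing tumor. From one labeled volume this module computes an
8-element per-subject feature vector:

* four *mean presence* values (``tC_M``, ``tnC_M``, ``Edm_M``, ``Nec_M``) —
  the voxel count of each descriptor divided by the number of tumor-bearing
  slices, i.e. average descriptor area per slice that contains tumor; and
* four *descriptor ratios* (``tC_R``, ``tnC_R``, ``Edm_R``, ``Nec_R``) —
  each mean presence normalized by the sum of all four, so the ratios lie on
  the probability simplex and describe tumor composition independent of size.

``tC`` refers to contrast-enhancing tumor, ``tnC`` to non-enhancing tumor,
``Edm`` to edema and ``Nec`` to necrosis.

The slice denominator counts slices containing at least one voxel of *any*
tumor label, shared by all four means, so the ratios have a common scale.
A volume with no tumor voxels has undefined features and is rejected.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, SchemaError, ValidationError

#: Default BRATS2015 label convention.
DEFAULT_LABEL_MAP: dict[str, int] = {
    "background": 0,
    "necrosis": 1,
    "edema": 2,
    "non_enhancing": 3,
    "enhancing": 4,
}

#: Descriptor role -> feature stem, in canonical feature order.
ROLE_TO_STEM: dict[str, str] = {
    "enhancing": "tC",
    "non_enhancing": "tnC",
    "edema": "Edm",
    "necrosis": "Nec",
}

DESCRIPTOR_ROLES: tuple[str, ...] = tuple(ROLE_TO_STEM)

MEAN_COLUMNS: tuple[str, ...] = ("tC_M", "tnC_M", "Edm_M", "Nec_M")
RATIO_COLUMNS: tuple[str, ...] = ("tC_R", "tnC_R", "Edm_R", "Nec_R")
FEATURE_COLUMNS: tuple[str, ...] = MEAN_COLUMNS + RATIO_COLUMNS
TABLE_COLUMNS: tuple[str, ...] = ("subject_id",) + FEATURE_COLUMNS


@dataclasses.dataclass
class SegmentationVolume:
    """A 3D integer label grid plus the role->integer label map it uses."""

    labels: np.ndarray
    label_map: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_LABEL_MAP)
    )

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError(
                f"segmentation grid must be 3D, got {self.labels.ndim}D"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.all(np.mod(self.labels, 1) == 0):
                self.labels = self.labels.astype(np.int64)
            else:
                raise ValidationError("segmentation grid must hold integer labels")
        missing = {"background", *DESCRIPTOR_ROLES} - set(self.label_map)
        if missing:
            raise ValidationError(f"label map missing roles: {sorted(missing)}")
        allowed = set(int(v) for v in self.label_map.values())
        present = set(int(v) for v in np.unique(self.labels))
        unknown = present - allowed
        if unknown:
            raise ValidationError(
                f"voxel value(s) {sorted(unknown)} not in label map {sorted(allowed)}"
            )

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    def tumor_mask(self) -> np.ndarray:
        """Boolean mask of voxels carrying any non-background label."""
        return self.labels != int(self.label_map["background"])


@dataclasses.dataclass
class DescriptorMeans:
    """Per-descriptor mean presence (voxels per tumor-bearing slice)."""

    tC_M: float
    tnC_M: float
    Edm_M: float
    Nec_M: float
    z_tumor: int

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.tC_M, self.tnC_M, self.Edm_M, self.Nec_M)


@dataclasses.dataclass
class FeatureVector:
    """The 8 per-subject features (4 mean presences + 4 composition ratios)."""

    subject_id: str
    tC_M: float
    tnC_M: float
    Edm_M: float
    Nec_M: float
    tC_R: float
    tnC_R: float
    Edm_R: float
    Nec_R: float
    label: object | None = None

    def __post_init__(self) -> None:
        for col in MEAN_COLUMNS:
            if getattr(self, col) < 0:
                raise ValidationError(f"{col} must be non-negative")
        for col in RATIO_COLUMNS:
            v = getattr(self, col)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{col}={v} outside [0, 1]")
        total = sum(getattr(self, c) for c in MEAN_COLUMNS)
        if total > 0:
            rsum = sum(getattr(self, c) for c in RATIO_COLUMNS)
            if abs(rsum - 1.0) > 1e-6:
                raise ValidationError(f"ratios sum to {rsum}, expected 1")

    def values(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in FEATURE_COLUMNS], dtype=float)


def read_segmentation(
    path: str | os.PathLike,
    label_map: Mapping[str, int] | None = None,
) -> SegmentationVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) label volume.

    The on-disk grid is returned indexed (x, y, z) with z the slice axis.
    Voxel values absent from ``label_map`` raise :class:`ValidationError`.
    """
    path = os.fspath(path)
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        arr = np.asanyarray(img.dataobj)
    elif lower.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        # SimpleITK arrays come back (z, y, x); restore (x, y, z).
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    else:
        raise ValidationError(f"unsupported segmentation format: {path}")
    return SegmentationVolume(arr, dict(label_map or DEFAULT_LABEL_MAP))


def write_segmentation(volume: SegmentationVolume, path: str | os.PathLike) -> None:
    """Write a label volume to NIfTI or MetaImage, inverse of read_segmentation."""
    path = os.fspath(path)
    lower = path.lower()
    data = volume.labels.astype(np.int16)
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(data, affine=np.eye(4)), path)
    elif lower.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        sitk.WriteImage(sitk.GetImageFromArray(data.transpose(2, 1, 0)), path)
    else:
        raise ValidationError(f"unsupported segmentation format: {path}")


def tumor_slice_count(volume: SegmentationVolume, slice_axis: int = 2) -> int:
    """Number of slices along ``slice_axis`` containing >=1 tumor voxel."""
    mask = volume.tumor_mask()
    other = tuple(ax for ax in range(3) if ax != slice_axis)
    return int(np.any(mask, axis=other).sum())


def descriptor_mean(
    volume: SegmentationVolume, role: str, slice_axis: int = 2
) -> float:
    """Mean presence of one descriptor: its voxel count / tumor-bearing slices.

    The denominator is the number of slices containing any tumor label, so
    it is shared across the four descriptors.
    """
    if role not in DESCRIPTOR_ROLES:
        raise DomainError(f"unknown descriptor role {role!r}; one of {DESCRIPTOR_ROLES}")
    z = tumor_slice_count(volume, slice_axis)
    if z == 0:
        raise DomainError("no tumor-bearing slices: descriptor means undefined")
    count = int((volume.labels == int(volume.label_map[role])).sum())
    return count / z


def compute_ratios(means: DescriptorMeans) -> tuple[float, float, float, float]:
    """Normalize the four mean presences onto the simplex (composition ratios)."""
    vals = means.as_tuple()
    if any(v < 0 for v in vals):
        raise DomainError("descriptor means must be non-negative")
    total = float(sum(vals))
    if total <= 0:
        raise DomainError("all descriptor means are zero: ratios undefined")
    return tuple(v / total for v in vals)  # type: ignore[return-value]


def compute_means(volume: SegmentationVolume, slice_axis: int = 2) -> DescriptorMeans:
    """All four descriptor mean presences plus the shared slice count."""
    z = tumor_slice_count(volume, slice_axis)
    if z == 0:
        raise DomainError("no tumor-bearing slices: descriptor means undefined")
    vals = {
        ROLE_TO_STEM[role] + "_M": descriptor_mean(volume, role, slice_axis)
        for role in DESCRIPTOR_ROLES
    }
    return DescriptorMeans(z_tumor=z, **vals)


def extract_features(
    volume: SegmentationVolume,
    subject_id: str,
    label: object | None = None,
    slice_axis: int = 2,
) -> FeatureVector:
    """Compute the full 8-feature vector for one subject."""
    means = compute_means(volume, slice_axis)
    tC_R, tnC_R, Edm_R, Nec_R = compute_ratios(means)
    return FeatureVector(
        subject_id=subject_id,
        tC_M=means.tC_M,
        tnC_M=means.tnC_M,
        Edm_M=means.Edm_M,
        Nec_M=means.Nec_M,
        tC_R=tC_R,
        tnC_R=tnC_R,
        Edm_R=Edm_R,
        Nec_R=Nec_R,
        label=label,
    )


def write_feature_table(
    vectors: Sequence[FeatureVector], path: str | os.PathLike
) -> None:
    """Write feature vectors as a UTF-8 CSV with a header row."""
    if not vectors:
        raise ValidationError("cannot write an empty feature table")
    rows = []
    with_labels = any(v.label is not None for v in vectors)
    for v in vectors:
        row = {"subject_id": v.subject_id}
        row.update({c: getattr(v, c) for c in FEATURE_COLUMNS})
        if with_labels:
            row["label"] = v.label
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_feature_table(path: str | os.PathLike) -> list[FeatureVector]:
    """Read a feature-table CSV back into validated FeatureVector records."""
    df = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table missing column(s): {missing}")
    has_label = "label" in df.columns
    vectors = []
    for _, row in df.iterrows():
        vectors.append(
            FeatureVector(
                subject_id=str(row["subject_id"]),
                label=row["label"] if has_label else None,
                **{c: float(row[c]) for c in FEATURE_COLUMNS},
            )
        )
    return vectors


def feature_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Feature vectors as a DataFrame (the in-memory training container)."""
    data = {"subject_id": [v.subject_id for v in vectors]}
    for c in FEATURE_COLUMNS:
        data[c] = [getattr(v, c) for v in vectors]
    if any(v.label is not None for v in vectors):
        data["label"] = [v.label for v in vectors]
    return pd.DataFrame(data)
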