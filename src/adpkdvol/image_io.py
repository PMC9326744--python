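"""Volume containers and DICOM/NIfTI readers and writers.

All volumes are held in a single canonical in-memory orientation with
grid axes ordered (right->left, anterior->posterior, inferior->superior),
i.e. nibabel axis codes ``('L', 'P', 'S')``.  Reorienting every input at
read time means the midline-splitting logic downstream never has to
reason about storage order.

Label maps follow the ITK-SNAP indices used for annotation: 1 = right
kidney (red), 2 = left kidney (green), 3 = spleen (blue), 4 = liver
(yellow).  A ``legacy-sum`` convention additionally permits diagnostic
overlap codes (sums of the claiming indices, e.g. 5 for a voxel claimed
by both right kidney and liver).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import pydicom

__all__ = [
    "CANONICAL_AXCODES",
    "ORGAN_LABELS",
    "LABEL_NAMES",
    "VolumeImage",
    "LabelMap",
    "ProbabilityMap",
    "LabelValidationReport",
    "read_dicom_series",
    "read_nifti",
    "write_nifti",
    "validate_labels",
]

#: Canonical grid-axis directions: +axis0 -> patient left, +axis1 ->
#: posterior, +axis2 -> superior.
CANONICAL_AXCODES: tuple[str, str, str] = ("L", "P", "S")

#: Organ name -> standard label index.
ORGAN_LABELS: dict[str, int] = {
    "right_kidney": 1,
    "left_kidney": 2,
    "spleen": 3,
    "liver": 4,
}
LABEL_NAMES: dict[int, str] = {v: k for k, v in ORGAN_LABELS.items()}

_STANDARD_VALUES = frozenset({0, 1, 2, 3, 4})


def _check_spacing(spacing_mm: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive lengths in mm, got {spacing_mm!r}")
    return spacing  # type: ignore[return-value]


@dataclass
class VolumeImage:
    """A 3D scalar intensity volume on a regular anisotropic lattice."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    orientation: tuple[str, str, str] = CANONICAL_AXCODES
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        self.spacing_mm = _check_spacing(self.spacing_mm)
        self.orientation = tuple(self.orientation)  # type: ignore[assignment]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class LabelMap:
    """A 3D integer organ label map congruent with a :class:`VolumeImage`.

    ``convention`` is ``"standard"`` (values restricted to {0..4}) or
    ``"legacy-sum"`` (diagnostic overlap codes permitted).
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    orientation: tuple[str, str, str] = CANONICAL_AXCODES
    convention: str = "standard"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D label map, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("label map data must be integer-valued")
            arr = np.round(arr)
        self.data = arr.astype(np.uint8)
        self.spacing_mm = _check_spacing(self.spacing_mm)
        self.orientation = tuple(self.orientation)  # type: ignore[assignment]
        if self.convention not in ("standard", "legacy-sum"):
            raise ValueError(f"unknown label convention {self.convention!r}")
        if self.convention == "standard":
            bad = sorted(set(np.unique(self.data)) - _STANDARD_VALUES)
            if bad:
                raise ValueError(
                    f"standard-convention label map contains out-of-convention "
                    f"value(s) {bad}; allowed values are 0-4"
                )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def congruent_with(self, other: "VolumeImage | LabelMap | ProbabilityMap") -> bool:
        return (
            self.grid_shape == other.grid_shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and tuple(self.orientation) == tuple(other.orientation)
        )


@dataclass
class ProbabilityMap:
    """Per-organ 3D probability volume on the native lattice."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    orientation: tuple[str, str, str] = CANONICAL_AXCODES
    organ: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D probability map, got shape {self.data.shape}")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 1):
            raise ValueError("probability map values must lie in [0, 1]")
        self.spacing_mm = _check_spacing(self.spacing_mm)
        self.orientation = tuple(self.orientation)  # type: ignore[assignment]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# orientation handling


def _canonicalize(data: np.ndarray, affine: np.ndarray) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Reorient ``data`` (with a RAS-space ``affine``) to canonical axes."""
    ornt = nib.orientations.io_orientation(affine)
    target = nib.orientations.axcodes2ornt(CANONICAL_AXCODES)
    transform = nib.orientations.ornt_transform(ornt, target)
    out = nib.orientations.apply_orientation(data, transform)
    zooms = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    perm = transform[:, 0].astype(int)
    spacing = tuple(float(zooms[p]) for p in perm)
    return np.ascontiguousarray(out), spacing  # type: ignore[return-value]


def _canonical_affine(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    """RAS affine for canonically oriented data (origin at zero)."""
    sx, sy, sz = spacing_mm
    aff = np.diag([-sx, -sy, sz, 1.0])
    return aff


# ---------------------------------------------------------------------------
# NIfTI


def read_nifti(path: str | Path, kind: str = "image") -> VolumeImage | LabelMap:
    """Read a NIfTI volume, reoriented to the canonical axes.

    Parameters
    ----------
    path:
        ``.nii`` or ``.nii.gz`` file.
    kind:
        ``"image"`` for a :class:`VolumeImage`, ``"labels"`` for a
        standard-convention :class:`LabelMap` (non-integer data or
        out-of-convention label values raise ``ValueError``).
    """
    if kind not in ("image", "labels"):
        raise ValueError(f"kind must be 'image' or 'labels', got {kind!r}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    canon, spacing = _canonicalize(data, img.affine)
    if kind == "image":
        return VolumeImage(canon.astype(np.float32), spacing, meta={"path": str(path)})
    if not np.allclose(canon, np.round(canon)):
        raise ValueError(f"{path}: non-integer data cannot be read as a label map")
    return LabelMap(np.round(canon).astype(np.int64), spacing, meta={"path": str(path)})


def write_nifti(obj: VolumeImage | LabelMap | ProbabilityMap, path: str | Path) -> Path:
    """Write a canonical volume as NIfTI; labels are stored as uint8."""
    if tuple(obj.orientation) != CANONICAL_AXCODES:
        raise ValueError("only canonically oriented volumes can be written")
    if isinstance(obj, LabelMap):
        data = obj.data.astype(np.uint8)
    else:
        data = obj.data.astype(np.float32)
    img = nib.Nifti1Image(data, _canonical_affine(obj.spacing_mm))
    img.header.set_zooms(obj.spacing_mm)
    nib.save(img, str(path))
    return Path(path)


# ---------------------------------------------------------------------------
# DICOM


def _plane_from_normal(normal: np.ndarray) -> str:
    axis = int(np.argmax(np.abs(normal)))
    return {0: "sagittal", 1: "coronal", 2: "axial"}[axis]


def read_dicom_series(directory: str | Path, slice_gap_tolerance: float = 0.01) -> VolumeImage:
    """Read a single-frame DICOM series from a directory.

    Slices are sorted by their through-plane position (projection of
    ImagePositionPatient onto the slice normal), so the result does not
    depend on file naming.  In-plane spacing comes from PixelSpacing and
    through-plane spacing from the median inter-slice gap; gaps deviating
    from the median by more than ``slice_gap_tolerance`` (relative) raise
    a warning and the median gap is used.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:  # non-DICOM clutter is skipped
            continue
    if not datasets:
        raise ValueError(f"{directory}: no readable DICOM files")

    uids = sorted({str(ds.SeriesInstanceUID) for ds in datasets})
    if len(uids) > 1:
        raise ValueError(
            f"{directory}: directory mixes {len(uids)} series "
            f"(SeriesInstanceUIDs: {', '.join(uids)})"
        )

    for ds in datasets:
        for tag in ("ImageOrientationPatient", "ImagePositionPatient", "PixelSpacing"):
            if getattr(ds, tag, None) is None:
                raise ValueError(f"{directory}: missing spatial metadata ({tag})")

    iop = np.asarray(datasets[0].ImageOrientationPatient, dtype=float)
    row_cos, col_cos = iop[:3], iop[3:]  # along increasing column / row index
    normal = np.cross(row_cos, col_cos)
    positions = np.array([float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal)) for ds in datasets])
    order = np.argsort(positions)
    datasets = [datasets[i] for i in order]
    positions = positions[order]

    if len(datasets) > 1:
        gaps = np.diff(positions)
        gap = float(np.median(gaps))
        if gap <= 0:
            raise ValueError(f"{directory}: degenerate slice positions")
        if np.any(np.abs(gaps - gap) > slice_gap_tolerance * gap):
            warnings.warn(
                f"{directory}: non-uniform slice gaps (range "
                f"{gaps.min():.3f}-{gaps.max():.3f} mm); using median {gap:.3f} mm",
                stacklevel=2,
            )
    else:
        gap = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)

    ps = [float(v) for v in datasets[0].PixelSpacing]  # (row spacing, col spacing)
    slope = float(getattr(datasets[0], "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(datasets[0], "RescaleIntercept", 0.0) or 0.0)
    slices = [ds.pixel_array.astype(np.float32) * slope + intercept for ds in datasets]
    vol = np.stack(slices, axis=-1)  # (row, col, slice)

    # LPS affine on array axes (row, col, slice), then LPS -> RAS.
    ipp0 = np.asarray(datasets[0].ImagePositionPatient, dtype=float)
    affine_lps = np.eye(4)
    affine_lps[:3, 0] = col_cos * ps[0]  # row index direction
    affine_lps[:3, 1] = row_cos * ps[1]  # column index direction
    if len(datasets) > 1:
        affine_lps[:3, 2] = (
            np.asarray(datasets[-1].ImagePositionPatient, float) - ipp0
        ) / (len(datasets) - 1)
    else:
        affine_lps[:3, 2] = normal * gap
    affine_lps[:3, 3] = ipp0
    affine_ras = np.diag([-1.0, -1.0, 1.0, 1.0]) @ affine_lps

    canon, spacing = _canonicalize(vol, affine_ras)
    meta = {
        "subject_id": str(getattr(datasets[0], "PatientID", "")),
        "series_description": str(getattr(datasets[0], "SeriesDescription", "")),
        "series_uid": uids[0],
        "plane": _plane_from_normal(normal),
        "n_slices": len(datasets),
    }
    return VolumeImage(canon, spacing, meta=meta)


# ---------------------------------------------------------------------------
# validation


@dataclass
class LabelValidationReport:
    """Per-label voxel counts plus convention violations (read-only)."""

    counts: dict[int, int]
    violations: list[int]
    missing_organs: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations

    def summary(self) -> str:
        lines = [f"label {v}: {n} voxels" for v, n in sorted(self.counts.items())]
        if self.violations:
            lines.append(f"out-of-convention values: {self.violations}")
        if self.missing_organs:
            lines.append(f"absent organs: {', '.join(self.missing_organs)}")
        return "\n".join(lines)


def validate_labels(label_map: LabelMap) -> LabelValidationReport:
    """Report per-label voxel counts and standard-convention violations."""
    values, counts = np.unique(label_map.data, return_counts=True)
    count_map = {int(v): int(c) for v, c in zip(values, counts)}
    violations = sorted(v for v in count_map if v not in _STANDARD_VALUES)
    missing = [LABEL_NAMES[v] for v in sorted(LABEL_NAMES) if v not in count_map]
    return LabelValidationReport(count_map, violations, missing)
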