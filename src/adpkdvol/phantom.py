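"""Synthetic abdominal phantom generator.

Emulates, at desk scale, the appearance of axial T2-weighted abdominal
MRI in ADPKD: four organs (right kidney, left kidney, spleen, liver)
modelled as piecewise-constant, pairwise non-overlapping ellipsoids on a
darker background, with bright spherical fluid-filled cysts rendered
inside the kidneys and liver, per-subject size/position variability,
anisotropic voxel spacing, and additive Gaussian noise.

A voxel belongs to an organ when its *center* lies inside the organ
ellipsoid, which keeps a brute-force point-in-ellipsoid scan an exact
oracle for the generated label maps.  Cysts change only the image
intensity; in the truth label map they belong to their host organ.

Coordinates follow the package-wide canonical axes: axis 0 runs patient
right -> left (the mid-sagittal plane is normal to it), axis 1 anterior
-> posterior, axis 2 inferior -> superior.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .image_io import ORGAN_LABELS, LabelMap, VolumeImage, write_nifti

__all__ = [
    "OrganEllipsoid",
    "CystPopulation",
    "PhantomSpec",
    "PhantomSubject",
    "PhantomOverlapError",
    "CohortVariability",
    "generate_phantom",
    "generate_cohort",
    "simulate_observer",
    "cohort_manifest",
    "write_cohort",
]


class PhantomOverlapError(ValueError):
    """Raised when two organ ellipsoids of a spec intersect on the grid."""


@dataclass
class OrganEllipsoid:
    """One organ: an axis-aligned ellipsoid in patient coordinates (mm)."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    intensity: float

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes_mm}")

    @property
    def volume_ml(self) -> float:
        """Analytic ellipsoid volume 4/3*pi*a*b*c, in mL."""
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0


@dataclass
class CystPopulation:
    """Spherical cysts drawn uniformly inside their host organ."""

    count: int = 0
    radius_range_mm: tuple[float, float] = (3.0, 10.0)
    intensity: float = 240.0

    def __post_init__(self) -> None:
        lo, hi = self.radius_range_mm
        if self.count < 0 or lo <= 0 or hi < lo:
            raise ValueError("invalid cyst parameters")


def _default_organs() -> dict[str, OrganEllipsoid]:
    # Positions/sizes roughly matching an enlarged ADPKD abdomen inside a
    # 352 x 352 x 180 mm field of view; midline at x = 176 mm.  T2-like
    # contrast ordering: liver < kidney parenchyma < spleen << cyst fluid.
    return {
        "right_kidney": OrganEllipsoid((100.0, 215.0, 80.0), (42.0, 32.0, 62.0), 110.0),
        "left_kidney": OrganEllipsoid((252.0, 215.0, 80.0), (42.0, 32.0, 62.0), 110.0),
        "spleen": OrganEllipsoid((268.0, 120.0, 128.0), (34.0, 26.0, 40.0), 150.0),
        "liver": OrganEllipsoid((108.0, 110.0, 128.0), (80.0, 52.0, 46.0), 85.0),
    }


def _default_cysts() -> dict[str, CystPopulation]:
    # ADPKD: heavily cystic kidneys, moderately cystic liver, spleen
    # enlarged but typically cyst-free.
    return {
        "right_kidney": CystPopulation(10, (3.0, 12.0)),
        "left_kidney": CystPopulation(10, (3.0, 12.0)),
        "spleen": CystPopulation(0),
        "liver": CystPopulation(5, (3.0, 10.0)),
    }


@dataclass
class PhantomSpec:
    """Full description of one phantom acquisition."""

    grid_shape: tuple[int, int, int] = (64, 64, 20)
    spacing_mm: tuple[float, float, float] = (5.5, 5.5, 9.0)
    organ_params: dict[str, OrganEllipsoid] = field(default_factory=_default_organs)
    cyst_params: dict[str, CystPopulation] = field(default_factory=_default_cysts)
    background_intensity: float = 45.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.grid_shape):
            raise ValueError("grid_shape entries must be >= 1")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.organ_params) - set(ORGAN_LABELS)
        if unknown:
            raise ValueError(f"unknown organs {sorted(unknown)}")
        mid = self.grid_shape[0] * self.spacing_mm[0] / 2.0
        for name, organ in self.organ_params.items():
            x = organ.center_mm[0]
            if name == "right_kidney" and x >= mid:
                raise ValueError("right kidney center must lie patient-right of midline")
            if name in ("left_kidney", "spleen") and x <= mid:
                raise ValueError(f"{name} center must lie patient-left of midline")


@dataclass
class PhantomSubject:
    """One simulated subject: image + ground-truth labels + strata tags."""

    image: VolumeImage
    truth: LabelMap
    height_m: float
    sequence_name: str
    subject_id: str

    def __post_init__(self) -> None:
        if not self.truth.congruent_with(self.image):
            raise ValueError("image and truth must share grid, spacing and orientation")


def _voxel_centers(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        (np.arange(n, dtype=np.float64) + 0.5) * s
        for n, s in zip(spec.grid_shape, spec.spacing_mm)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)  # type: ignore[return-value]


def _ellipsoid_mask(spec: PhantomSpec, organ: OrganEllipsoid) -> np.ndarray:
    xs, ys, zs = _voxel_centers(spec)
    cx, cy, cz = organ.center_mm
    ax, ay, az = organ.semi_axes_mm
    r2 = ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 + ((zs - cz) / az) ** 2
    return r2 <= 1.0


def _sample_cyst_centers(
    rng: np.random.Generator, organ: OrganEllipsoid, radii: np.ndarray
) -> np.ndarray:
    """Cyst centers uniform in the ellipsoid, each sphere fully inside."""
    centers = np.empty((len(radii), 3))
    semi = np.asarray(organ.semi_axes_mm)
    for i, r in enumerate(radii):
        shrink = max(0.0, 1.0 - r / semi.min())
        while True:
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            rho = rng.random() ** (1.0 / 3.0)
            p = u * rho * shrink
            if np.sum(p**2) <= shrink**2 + 1e-12:
                centers[i] = np.asarray(organ.center_mm) + p * semi
                break
    return centers


def generate_phantom(spec: PhantomSpec) -> PhantomSubject:
    """Render one phantom subject from its spec.

    Raises :class:`PhantomOverlapError` naming the first colliding organ
    pair if any two organ ellipsoids claim the same voxel.
    """
    masks = {name: _ellipsoid_mask(spec, organ) for name, organ in spec.organ_params.items()}
    names = list(masks)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if np.any(masks[a] & masks[b]):
                raise PhantomOverlapError(
                    f"organ ellipsoids overlap: {a} and {b} claim common voxels"
                )

    truth = np.zeros(spec.grid_shape, dtype=np.uint8)
    image = np.full(spec.grid_shape, spec.background_intensity, dtype=np.float64)
    for name, mask in masks.items():
        truth[mask] = ORGAN_LABELS[name]
        image[mask] = spec.organ_params[name].intensity

    rng = np.random.default_rng(spec.seed)
    xs, ys, zs = _voxel_centers(spec)
    for name in sorted(spec.cyst_params):  # fixed order for reproducibility
        cysts = spec.cyst_params[name]
        if name not in spec.organ_params or cysts.count == 0:
            continue
        lo, hi = cysts.radius_range_mm
        radii = rng.uniform(lo, hi, size=cysts.count)
        centers = _sample_cyst_centers(rng, spec.organ_params[name], radii)
        for (cx, cy, cz), r in zip(centers, radii):
            sphere = (xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2 <= r**2
            image[sphere] = cysts.intensity

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)

    vol = VolumeImage(image.astype(np.float32), spec.spacing_mm, meta={"phantom_seed": spec.seed})
    lab = LabelMap(truth, spec.spacing_mm)
    return PhantomSubject(vol, lab, height_m=1.70, sequence_name="ssfse", subject_id=f"phantom{spec.seed:04d}")


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortVariability:
    """Per-subject jitter applied to the base spec.

    ``size_sd`` is the SD of a log-normal scale factor applied to organ
    semi-axes (one factor shared by both kidneys so TKV varies smoothly,
    independent factors for liver and spleen); ``position_jitter_mm`` is
    the half-width of a uniform shift of each organ center.
    """

    size_sd: float = 0.12
    position_jitter_mm: float = 5.0
    height_mean_m: float = 1.70
    height_sd_m: float = 0.09
    sequence_names: tuple[str, ...] = ("ssfse", "haste")


def _jittered_spec(
    base: PhantomSpec, var: CohortVariability, rng: np.random.Generator, seed: int
) -> PhantomSpec:
    organs: dict[str, OrganEllipsoid] = {}
    kidney_scale = float(np.exp(rng.normal(0.0, var.size_sd)))
    for name, organ in base.organ_params.items():
        if name in ("right_kidney", "left_kidney"):
            scale = kidney_scale * float(np.exp(rng.normal(0.0, var.size_sd / 3)))
        else:
            scale = float(np.exp(rng.normal(0.0, var.size_sd)))
        shift = rng.uniform(-var.position_jitter_mm, var.position_jitter_mm, size=3)
        organs[name] = OrganEllipsoid(
            tuple(np.asarray(organ.center_mm) + shift),
            tuple(np.asarray(organ.semi_axes_mm) * scale),
            organ.intensity,
        )
    return replace(base, organ_params=organs, seed=seed)


def generate_cohort(
    n_subjects: int,
    variability: CohortVariability | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    max_attempts: int = 50,
) -> list[PhantomSubject]:
    """Generate a reproducible cohort of jittered phantom subjects.

    Jittered geometries that violate the non-overlap invariant are
    redrawn (up to ``max_attempts`` per subject).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    var = variability if variability is not None else CohortVariability()
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    subjects: list[PhantomSubject] = []
    for i in range(n_subjects):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        for attempt in range(max_attempts):
            spec = _jittered_spec(base, var, rng, seed=sub_seed)
            try:
                subject = generate_phantom(spec)
            except PhantomOverlapError:
                if attempt == max_attempts - 1:
                    raise
                continue
            break
        height = float(np.clip(rng.normal(var.height_mean_m, var.height_sd_m), 1.4, 2.1))
        subject.height_m = height
        subject.sequence_name = str(rng.choice(list(var.sequence_names)))
        subject.subject_id = f"subj{i:03d}"
        subjects.append(subject)
    return subjects


def truth_volume_ml(truth: LabelMap, label: int) -> float:
    return float(np.count_nonzero(truth.data == label) * truth.voxel_volume_mm3 / 1000.0)


def cohort_manifest(subjects: list[PhantomSubject]) -> pd.DataFrame:
    """Subject-level manifest: id, height, sequence tag and truth TKV."""
    rows = []
    for s in subjects:
        tkv = truth_volume_ml(s.truth, 1) + truth_volume_ml(s.truth, 2)
        rows.append(
            {
                "subject_id": s.subject_id,
                "height_m": s.height_m,
                "sequence_name": s.sequence_name,
                "tkv_ml": tkv,
            }
        )
    return pd.DataFrame(rows)


def write_cohort(subjects: list[PhantomSubject], out_dir: str | Path) -> Path:
    """Write image/truth NIfTI pairs plus ``manifest.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        write_nifti(s.image, out / f"{s.subject_id}_image.nii.gz")
        write_nifti(s.truth, out / f"{s.subject_id}_truth.nii.gz")
    manifest = cohort_manifest(subjects)
    manifest.to_csv(out / "manifest.csv", index=False)
    return out


# ---------------------------------------------------------------------------
# observer simulation


def simulate_observer(truth: LabelMap, boundary_noise_mm: float, seed: int = 0) -> LabelMap:
    """Perturb organ boundaries to mimic an independent human observer.

    Each organ's signed distance field (positive inside, mm) is shifted
    by a smooth Gaussian random field with pointwise SD
    ``boundary_noise_mm``, and the organ is re-extracted as the positive
    set.  Organ identities never change; with zero noise the truth is
    returned unchanged.  Voxels claimed by several perturbed organs go to
    the lowest label index (kidneys first), keeping one label per voxel.
    """
    from scipy import ndimage

    if boundary_noise_mm < 0:
        raise ValueError("boundary_noise_mm must be >= 0")
    if boundary_noise_mm == 0:
        return copy.deepcopy(truth)

    rng = np.random.default_rng(seed)
    out = np.zeros_like(truth.data)
    spacing = truth.spacing_mm
    for label in sorted(int(v) for v in np.unique(truth.data) if v != 0):
        mask = truth.data == label
        inside = ndimage.distance_transform_edt(mask, sampling=spacing)
        outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
        # Center the zero level on the mask surface (EDT measures to voxel
        # centers, so boundary voxels sit one full spacing from "outside").
        half = min(spacing) / 2.0
        sdt = np.where(mask, inside - half, -(outside - half))
        field = ndimage.gaussian_filter(rng.standard_normal(truth.grid_shape), sigma=2.0)
        sd = field.std()
        if sd > 0:
            field *= boundary_noise_mm / sd
        new_mask = (sdt + field) > 0
        out[new_mask & (out == 0)] = label
    return LabelMap(out, truth.spacing_mm, truth.orientation)
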