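"""Multi-organ ensemble inference: thresholding, overlap adjudication,
midline kidney splitting.

Each of the three binary models claims voxels independently, so a voxel
can exceed the 50% probability cutoff for more than one organ (typically
at the kidney/liver interface).  Conflicts are resolved by a fixed
priority — kidney first, then spleen, then liver — which encodes the
empirical rule that kidney/liver overlap voxels belong to the kidney.
The merged kidney class is then split into right (label 1) and left
(label 2) at the mid-sagittal plane of the volume.

A legacy diagnostic encoding is kept for visual audit: overlap voxels
get the *sum* of the claiming label indices (right kidney 1 + liver 4 =
pink 5 in ITK-SNAP).  The sum code is ambiguous (2+3 also gives 5) and
is never used for volumetry.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import LabelMap, ProbabilityMap, VolumeImage, CANONICAL_AXCODES
from .model import OrganCheckpoint, predict_volume

__all__ = [
    "PRIORITY_ORDER",
    "OrganClaims",
    "SumEncodingAudit",
    "infer_organ",
    "threshold_claims",
    "adjudicate_priority",
    "encode_overlaps_sum",
    "split_kidneys_midline",
    "run_ensemble",
]

#: Adjudication priority, highest first, with the provisional label each
#: class receives (the merged kidney class provisionally takes the
#: right-kidney index 1 until the midline split).
PRIORITY_ORDER: tuple[tuple[str, int], ...] = (("kidney", 1), ("spleen", 3), ("liver", 4))

_SUM_CODES = {"kidney": 1, "right_kidney": 1, "left_kidney": 2, "spleen": 3, "liver": 4}


@dataclass
class OrganClaims:
    """Per-class probability maps on a shared native grid."""

    maps: dict[str, ProbabilityMap]
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.maps:
            raise ValueError("at least one organ claim is required")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        ref = next(iter(self.maps.values()))
        for name, pm in self.maps.items():
            if pm.grid_shape != ref.grid_shape or not np.allclose(pm.spacing_mm, ref.spacing_mm):
                raise ValueError(f"claim {name!r} is not congruent with the others")


def infer_organ(image: VolumeImage, ckpt: OrganCheckpoint) -> ProbabilityMap:
    """Run one organ's checkpoint over a volume, slice by slice."""
    if tuple(image.orientation) != CANONICAL_AXCODES:
        raise ValueError("image must be in canonical orientation before inference")
    net = ckpt.model()
    prob = predict_volume(net, image, ckpt.preprocess)
    return ProbabilityMap(prob, image.spacing_mm, image.orientation, organ=ckpt.organ)


def threshold_claims(claims: OrganClaims) -> dict[str, np.ndarray]:
    """Binary masks: a voxel is positive iff probability > threshold.

    The inequality is strict, so a probability of exactly 0.5 at the
    default cutoff is negative.
    """
    return {name: pm.data > claims.threshold for name, pm in claims.maps.items()}


def adjudicate_priority(masks: dict[str, np.ndarray]) -> LabelMap | np.ndarray:
    """Resolve multi-organ claims: each voxel goes to the single
    highest-priority claiming class (kidney > spleen > liver).

    Accepts masks keyed by class name; returns a plain uint8 array with
    values {0, 1 (kidney, provisional), 3, 4}.  No claimed voxel is ever
    discarded: the adjudicated foreground equals the union of claims.
    """
    unknown = set(masks) - {name for name, _ in PRIORITY_ORDER}
    if unknown:
        raise ValueError(f"unknown organ classes {sorted(unknown)}")
    shapes = {m.shape for m in masks.values()}
    if len(shapes) > 1:
        raise ValueError("claim masks must be congruent")
    ref = next(iter(masks.values()))
    out = np.zeros(ref.shape, dtype=np.uint8)
    for name, label in PRIORITY_ORDER:  # highest priority first
        if name in masks:
            out[(out == 0) & masks[name]] = label
    return out


@dataclass
class SumEncodingAudit:
    """Bookkeeping for the legacy sum-color diagnostic encoding."""

    n_overlap_voxels: int
    overlap_codes: list[int] = field(default_factory=list)
    ambiguous_codes: dict[int, list[tuple[str, ...]]] = field(default_factory=dict)

    @property
    def has_ambiguity(self) -> bool:
        return bool(self.ambiguous_codes)


def encode_overlaps_sum(
    masks: dict[str, np.ndarray], spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> tuple[LabelMap, SumEncodingAudit]:
    """Legacy diagnostic encoding: overlap voxels get the sum of the
    claiming label indices (e.g. right kidney 1 + liver 4 -> pink 5).

    Returns the sum-coded map (``legacy-sum`` convention) plus an audit
    report flagging ambiguous codes — sums that coincide either with each
    other (left kidney 2 + spleen 3 = 5 = right kidney 1 + liver 4) or
    with a plain single-organ index.  Intended for visual review only.
    """
    unknown = set(masks) - set(_SUM_CODES)
    if unknown:
        raise ValueError(f"unknown organ classes {sorted(unknown)}")
    shapes = {m.shape for m in masks.values()}
    if len(shapes) != 1:
        raise ValueError("need at least one mask; all masks must be congruent")

    names = sorted(masks, key=lambda n: _SUM_CODES[n])
    stack = np.stack([np.asarray(masks[n], dtype=bool) for n in names])
    codes = np.asarray([_SUM_CODES[n] for n in names])
    claims = stack.sum(axis=0)
    summed = np.tensordot(codes, stack.astype(np.uint8), axes=1).astype(np.uint8)
    out = np.where(claims > 0, summed, 0).astype(np.uint8)

    # every claim subset of size >= 2 that could collide, given these organs
    from itertools import combinations

    sums: dict[int, list[tuple[str, ...]]] = {}
    for r in range(2, len(names) + 1):
        for combo in combinations(names, r):
            sums.setdefault(sum(_SUM_CODES[n] for n in combo), []).append(combo)
    ambiguous = {
        code: combos
        for code, combos in sums.items()
        if len(combos) > 1 or code in set(codes.tolist())
    }
    audit = SumEncodingAudit(
        n_overlap_voxels=int((claims > 1).sum()),
        overlap_codes=sorted(int(c) for c in np.unique(out[claims > 1])),
        ambiguous_codes=ambiguous,
    )
    label_map = LabelMap(out, spacing_mm, convention="legacy-sum")
    return label_map, audit


def split_kidneys_midline(
    label_data: LabelMap | np.ndarray,
    spacing_mm: tuple[float, float, float] | None = None,
    orientation: tuple[str, str, str] | None = None,
    kidney_label: int = 1,
) -> LabelMap:
    """Split the provisional kidney class at the mid-sagittal plane.

    Kidney voxels strictly patient-left of the volume midline become the
    left kidney (label 2); all others, including voxels exactly on the
    plane, stay right kidney (label 1).  Other labels are untouched.  The
    first grid axis must run patient right -> left (canonical
    orientation); anything else is an error.
    """
    if isinstance(label_data, LabelMap):
        arr = label_data.data
        spacing = label_data.spacing_mm
        orient = label_data.orientation
    else:
        arr = np.asarray(label_data)
        spacing = spacing_mm if spacing_mm is not None else (1.0, 1.0, 1.0)
        orient = orientation
    if orient is None or tuple(orient) != CANONICAL_AXCODES:
        raise ValueError(
            f"midline split requires canonical orientation {CANONICAL_AXCODES}, got {orient}"
        )
    out = arr.astype(np.uint8).copy()
    mid = (arr.shape[0] - 1) / 2.0
    xi = np.arange(arr.shape[0])[:, None, None]
    left_of_midline = xi > mid  # strictly patient-left
    kidney = arr == kidney_label
    out[kidney & left_of_midline] = 2
    out[kidney & ~left_of_midline] = 1
    return LabelMap(out, spacing, CANONICAL_AXCODES)


def run_ensemble(
    image: VolumeImage,
    checkpoints: dict[str, OrganCheckpoint],
    threshold: float = 0.5,
    return_claims: bool = False,
) -> LabelMap | tuple[LabelMap, OrganClaims]:
    """Full multi-organ inference on one volume.

    Runs the kidney, spleen and liver checkpoints, thresholds at
    ``threshold``, adjudicates overlaps by priority and splits the
    kidneys at the midline; the result is a standard-convention label
    map on the input grid.
    """
    missing = set(("kidney", "spleen", "liver")) - set(checkpoints)
    if missing:
        raise ValueError(f"missing checkpoints for {sorted(missing)}")
    claims = OrganClaims(
        {organ: infer_organ(image, ckpt) for organ, ckpt in checkpoints.items()},
        threshold=threshold,
    )
    masks = threshold_claims(claims)
    provisional = adjudicate_priority(masks)
    result = split_kidneys_midline(provisional, image.spacing_mm, CANONICAL_AXCODES)
    if return_claims:
        return result, claims
    return result
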