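"""Organ volumetry and agreement statistics.

Implements the evaluation suite used to compare automated segmentations
against ground-truth contours and to quantify interobserver variability:

* Dice similarity coefficient ``DSC = 2|A ∩ B| / (|A| + |B|)``,
* Lin's concordance correlation coefficient,
* RMSE and mean absolute percent error of organ volumes,
* the count of cases with zero volume error at 1 mL rounding,
* Bland–Altman bias and 95% limits of agreement on a percent scale,
* per-case interobserver SD and the two-way random-effects,
  absolute-agreement, single-rater ICC(2,1).

Volumes are voxel counts times voxel volume; TKV is the sum of the two
kidney volumes and ht-TKV is TKV divided by subject height in meters.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image_io import LABEL_NAMES, ORGAN_LABELS, LabelMap

__all__ = [
    "organ_volume",
    "VolumeReport",
    "volume_report",
    "dsc",
    "concordance",
    "rmse",
    "mean_percent_error",
    "zero_error_count",
    "BlandAltman",
    "bland_altman",
    "plot_bland_altman",
    "interobserver_sd",
    "icc",
    "AgreementReport",
    "evaluate_run",
]


def organ_volume(label_map: LabelMap, label: int, spacing_mm: tuple[float, float, float] | None = None) -> float:
    """Volume of one label in mL: voxel count × voxel volume / 1000."""
    spacing = spacing_mm if spacing_mm is not None else label_map.spacing_mm
    voxel_mm3 = float(np.prod(spacing))
    return float(np.count_nonzero(label_map.data == label) * voxel_mm3 / 1000.0)


@dataclass
class VolumeReport:
    """Per-organ volumes for one study, with TKV and height-adjusted TKV."""

    right_kidney_ml: float
    left_kidney_ml: float
    spleen_ml: float
    liver_ml: float
    height_m: float | None = None

    @property
    def tkv_ml(self) -> float:
        return self.right_kidney_ml + self.left_kidney_ml

    @property
    def ht_tkv_ml_per_m(self) -> float | None:
        if self.height_m is None:
            return None
        return self.tkv_ml / self.height_m

    def to_frame(self) -> pd.DataFrame:
        rows = {name: getattr(self, f"{name}_ml") for name in ORGAN_LABELS}
        rows["tkv"] = self.tkv_ml
        if self.ht_tkv_ml_per_m is not None:
            rows["ht_tkv_per_m"] = self.ht_tkv_ml_per_m
        return pd.DataFrame({"structure": list(rows), "volume_ml": list(rows.values())})


def volume_report(label_map: LabelMap, height_m: float | None = None) -> VolumeReport:
    return VolumeReport(
        right_kidney_ml=organ_volume(label_map, 1),
        left_kidney_ml=organ_volume(label_map, 2),
        spleen_ml=organ_volume(label_map, 3),
        liver_ml=organ_volume(label_map, 4),
        height_m=height_m,
    )


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient of two binary masks.

    Two empty masks score 1.0: an organ absent from both segmentations is
    perfect agreement.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must be congruent")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def concordance(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length series with n >= 2")
    mx, my = x.mean(), y.mean()
    sx2 = ((x - mx) ** 2).mean()
    sy2 = ((y - my) ** 2).mean()
    sxy = ((x - mx) * (y - my)).mean()
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValueError("concordance undefined: both series constant and equal")
    return float(2.0 * sxy / denom)


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must be equal length")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def mean_percent_error(x: np.ndarray, y: np.ndarray) -> float:
    """Mean absolute per-case percent error of ``y`` against truth ``x``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must be equal length")
    if np.any(x == 0):
        raise ValueError("percent error undefined for zero truth volumes")
    return float(np.mean(np.abs(y - x) / np.abs(x)) * 100.0)


def zero_error_count(x: np.ndarray, y: np.ndarray, rounding_ml: float = 1.0) -> int:
    """Number of cases whose volumes agree after rounding to ``rounding_ml``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must be equal length")
    return int(np.sum(np.round(x / rounding_ml) == np.round(y / rounding_ml)))


@dataclass
class BlandAltman:
    """Bland–Altman payload on a percent scale (difference = y − x)."""

    means: np.ndarray
    diffs_percent: np.ndarray
    bias: float
    lower_limit: float
    upper_limit: float


def bland_altman(x: np.ndarray, y: np.ndarray) -> BlandAltman:
    """Percent-scale Bland–Altman analysis of ``y`` against ``x``.

    Each case contributes ``(y - x) / mean(x, y) × 100`` plotted against
    the case mean; bias is the mean difference and the 95% limits are
    bias ± 1.96 SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("need two equal-length 1D series")
    means = (x + y) / 2.0
    if np.any(means == 0):
        raise ValueError("percent differences undefined when a case mean is zero")
    diffs = (y - x) / means * 100.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0
    return BlandAltman(means, diffs, bias, bias - 1.96 * sd, bias + 1.96 * sd)


def plot_bland_altman(ba: BlandAltman, path: str, title: str = "") -> str:
    """Write the Bland–Altman scatter with bias/limit lines to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.means, ba.diffs_percent, s=14, alpha=0.7)
    ax.axhline(ba.bias, color="k", lw=1, label=f"bias {ba.bias:.1f}%")
    for lim in (ba.lower_limit, ba.upper_limit):
        ax.axhline(lim, color="r", ls="--", lw=1)
    ax.set_xlabel("mean volume (mL)")
    ax.set_ylabel("difference (%)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def interobserver_sd(measurements: np.ndarray) -> float:
    """Mean over cases of the per-case sample SD across observers.

    ``measurements`` is (n_cases, n_observers), in mL.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need an (n_cases, n_observers>=2) table")
    return float(m.std(axis=1, ddof=1).mean())


def icc(measurements: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Computed from the two-way ANOVA mean squares of an
    (n_cases, k_observers) table::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 cases and 2 observers")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((m - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("ICC undefined: zero total variance")
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# run-level evaluation


@dataclass
class AgreementReport:
    """Per-organ agreement metrics for a set of truth/prediction pairs."""

    table: pd.DataFrame
    bland_altman_payloads: dict[str, BlandAltman] = field(default_factory=dict)
    n_cases: int = 0

    def to_csv(self, path: str) -> str:
        self.table.to_csv(path, index=False)
        return path


def evaluate_run(
    truths: list[LabelMap],
    predictions: list[LabelMap],
    manifest: pd.DataFrame | None = None,
) -> AgreementReport:
    """Compare predicted label maps against truths, organ by organ.

    For each organ: mean DSC over cases, Lin's concordance of volumes
    (NaN when fewer than two cases), RMSE (mL), mean absolute percent
    error, zero-error count at 1 mL rounding, and percent-scale
    Bland–Altman bias/limits.
    """
    if len(truths) != len(predictions) or not truths:
        raise ValueError("need equal, nonzero numbers of truths and predictions")
    for t, p in zip(truths, predictions):
        if not t.congruent_with(p):
            raise ValueError("truth/prediction pair not congruent")

    rows = []
    payloads: dict[str, BlandAltman] = {}
    n = len(truths)
    for label, organ in sorted(LABEL_NAMES.items()):
        dscs = [dsc(t.data == label, p.data == label) for t, p in zip(truths, predictions)]
        vx = np.array([organ_volume(t, label) for t in truths])
        vy = np.array([organ_volume(p, label) for p in predictions])
        ccc = concordance(vx, vy) if n >= 2 and (vx.var() + vy.var()) > 0 else np.nan
        pct = mean_percent_error(vx, vy) if np.all(vx > 0) else np.nan
        row = {
            "organ": organ,
            "n": n,
            "dsc": float(np.mean(dscs)),
            "concordance": ccc,
            "rmse_ml": rmse(vx, vy),
            "mean_percent_error": pct,
            "zero_error_count": zero_error_count(vx, vy),
        }
        if np.all((vx + vy) > 0):
            ba = bland_altman(vx, vy)
            payloads[organ] = ba
            row.update(
                ba_bias_percent=ba.bias,
                ba_lower_percent=ba.lower_limit,
                ba_upper_percent=ba.upper_limit,
            )
        else:
            row.update(ba_bias_percent=np.nan, ba_lower_percent=np.nan, ba_upper_percent=np.nan)
        rows.append(row)
    return AgreementReport(pd.DataFrame(rows), payloads, n_cases=n)
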