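"""Per-organ binary segmentation models: targets, loss, split, training.

Three binary 2D networks are trained independently — one for the kidneys
(right and left merged into a single class, which trains better than
separating them), one for the spleen, one for the liver.  Training
minimizes soft dice plus binary cross-entropy, optimized by RAdam
wrapped in Lookahead with batch size 8; after every epoch the volume-wise
validation Dice is computed and the best-scoring epoch's weights become
the checkpoint.  Convergence is declared when the validation Dice stops
improving for ``patience`` epochs.

Subjects are assigned to train/validation as whole subjects (all scans
of a subject co-assigned), stratified by TKV quartile crossed with pulse
sequence name.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .image_io import LabelMap, VolumeImage
from .metrics import dsc
from .nn import ArchConfig, Lookahead, RAdam, UNet2D, build_model
from .phantom import PhantomSubject
from .preprocess import PreprocessConfig, augment, infer_transform, minmax_normalize, restore_native, train_transform

__all__ = [
    "ORGAN_CLASSES",
    "TrainConfig",
    "OrganCheckpoint",
    "SplitSpec",
    "merge_kidney_labels",
    "binary_target",
    "combined_loss",
    "stratified_split",
    "train_organ",
    "predict_volume",
]

#: The three model classes; "kidney" covers both kidneys as one class.
ORGAN_CLASSES = ("kidney", "spleen", "liver")
_ORGAN_TARGET_LABELS = {"spleen": (3,), "liver": (4,), "kidney": (1, 2)}


def merge_kidney_labels(label_map: LabelMap) -> np.ndarray:
    """Binary mask of both kidneys (labels 1 and 2) as a single class."""
    if label_map.convention != "standard":
        raise ValueError("kidney merging requires the standard label convention")
    return np.isin(label_map.data, (1, 2))


def binary_target(label_map: LabelMap, organ: str) -> np.ndarray:
    """Binary training target for one organ class."""
    if organ == "kidney":
        return merge_kidney_labels(label_map)
    if organ not in _ORGAN_TARGET_LABELS:
        raise ValueError(f"unknown organ class {organ!r}; expected one of {ORGAN_CLASSES}")
    return np.isin(label_map.data, _ORGAN_TARGET_LABELS[organ])


@dataclass
class TrainConfig:
    organ: str = "kidney"
    batch_size: int = 8
    max_epochs: int = 30
    lr: float = 5e-3
    w_dice: float = 1.0
    w_ce: float = 1.0
    dice_eps: float = 1.0
    patience: int = 10
    lookahead_k: int = 5
    lookahead_alpha: float = 0.5
    encoder: str = "tiny"
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)

    def __post_init__(self) -> None:
        if self.organ not in ORGAN_CLASSES:
            raise ValueError(f"organ must be one of {ORGAN_CLASSES}, got {self.organ!r}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.dice_eps <= 0:
            raise ValueError("dice smoothing eps must be > 0")
        if isinstance(self.preprocess, dict):
            self.preprocess = PreprocessConfig.from_dict(self.preprocess)


def combined_loss(
    pred: np.ndarray, target: np.ndarray, cfg: TrainConfig | None = None
) -> float:
    """Soft dice loss plus mean binary cross-entropy.

    ``loss = w_d (1 - (2 Σ p g + ε) / (Σ p + Σ g + ε)) + w_ce BCE`` with
    predictions ``p`` in [0, 1] and binary targets ``g``.
    """
    cfg = cfg or TrainConfig()
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(target, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError("pred and target must be congruent")
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("predictions must lie in [0, 1]")
    eps = cfg.dice_eps
    dice_term = 1.0 - (2.0 * (p * g).sum() + eps) / (p.sum() + g.sum() + eps)
    pc = np.clip(p, 1e-7, 1.0 - 1e-7)
    ce_term = float(-(g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)).mean())
    return float(cfg.w_dice * dice_term + cfg.w_ce * ce_term)


def _loss_and_logit_grad(
    logits: np.ndarray, target: np.ndarray, cfg: TrainConfig
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient w.r.t. the logits, in one pass."""
    z = logits.astype(np.float64)
    g = target.astype(np.float64)
    p = 1.0 / (1.0 + np.exp(-z))
    eps = cfg.dice_eps
    num = 2.0 * (p * g).sum() + eps
    den = p.sum() + g.sum() + eps
    dice_term = 1.0 - num / den
    # stable BCE-with-logits
    ce = np.maximum(z, 0) - z * g + np.log1p(np.exp(-np.abs(z)))
    n = z.size
    loss = cfg.w_dice * dice_term + cfg.w_ce * float(ce.mean())
    ddice_dp = -(2.0 * g * den - num) / den**2
    dz = cfg.w_dice * ddice_dp * p * (1.0 - p) + cfg.w_ce * (p - g) / n
    return float(loss), dz


# ---------------------------------------------------------------------------
# stratified subject split


@dataclass
class SplitSpec:
    """Per-subject train/validation assignment with its strata table."""

    assignment: dict[str, str]  # subject_id -> "train" | "val"
    strata: pd.DataFrame | None = None

    def subjects(self, partition: str) -> list[str]:
        return sorted(s for s, p in self.assignment.items() if p == partition)

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(self.assignment, indent=2))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitSpec":
        return cls(json.loads(Path(path).read_text()))


def stratified_split(manifest: pd.DataFrame, fraction: float = 0.7, seed: int = 0) -> SplitSpec:
    """Split subjects into train/validation, stratified by TKV quartile
    crossed with pulse sequence name.

    ``manifest`` needs columns ``subject_id``, ``tkv_ml`` and
    ``sequence_name``; repeated rows per subject (multiple scans) are
    allowed and are co-assigned.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    subjects = (
        manifest.groupby("subject_id")
        .agg(tkv_ml=("tkv_ml", "mean"), sequence_name=("sequence_name", "first"))
        .reset_index()
    )
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects to split")
    try:
        subjects["tkv_bin"] = pd.qcut(subjects["tkv_ml"], 4, labels=False, duplicates="drop")
    except ValueError:
        subjects["tkv_bin"] = 0
    subjects["tkv_bin"] = subjects["tkv_bin"].fillna(0)

    rng = np.random.default_rng(seed)
    strata_ids: list[list[str]] = []
    for _, group in subjects.groupby(["tkv_bin", "sequence_name"], sort=True):
        ids = list(group["subject_id"])
        rng.shuffle(ids)
        strata_ids.append(ids)

    # largest-remainder allocation so the global train count hits the
    # requested fraction even when strata are small
    quotas = [fraction * len(ids) for ids in strata_ids]
    floors = [int(np.floor(q)) for q in quotas]
    target = int(round(fraction * len(subjects)))
    leftover = max(0, target - sum(floors))
    order = np.argsort([floors[i] - quotas[i] for i in range(len(quotas))], kind="stable")
    n_train_per = list(floors)
    for i in order[:leftover]:
        if n_train_per[i] < len(strata_ids[i]):
            n_train_per[i] += 1

    assignment: dict[str, str] = {}
    for ids, n_train in zip(strata_ids, n_train_per):
        for sid in ids[:n_train]:
            assignment[sid] = "train"
        for sid in ids[n_train:]:
            assignment[sid] = "val"
    # guarantee both partitions are populated
    parts = set(assignment.values())
    ids_sorted = sorted(assignment)
    if "val" not in parts:
        assignment[ids_sorted[-1]] = "val"
    if "train" not in set(assignment.values()):
        assignment[ids_sorted[0]] = "train"
    return SplitSpec(assignment, strata=subjects)


# ---------------------------------------------------------------------------
# checkpoints


@dataclass
class OrganCheckpoint:
    """A trained binary model plus everything needed to rerun it."""

    organ: str
    state: dict[str, np.ndarray]
    arch: ArchConfig
    preprocess: PreprocessConfig
    best_val_dsc: float
    best_epoch: int
    log: pd.DataFrame | None = None

    def model(self) -> UNet2D:
        net = build_model(self.arch)
        net.load_state_dict(self.state)
        return net

    def save(self, path: str | Path) -> Path:
        meta = {
            "organ": self.organ,
            "arch": self.arch.to_dict(),
            "preprocess": self.preprocess.to_dict(),
            "best_val_dsc": self.best_val_dsc,
            "best_epoch": self.best_epoch,
            "log": self.log.to_dict(orient="list") if self.log is not None else None,
        }
        arrays = {f"param::{k}": v for k, v in self.state.items()}
        np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
        return Path(path)

    @classmethod
    def load(cls, path: str | Path) -> "OrganCheckpoint":
        with np.load(path) as npz:
            meta = json.loads(npz["__meta__"].tobytes().decode())
            state = {k.removeprefix("param::"): npz[k] for k in npz.files if k.startswith("param::")}
        return cls(
            organ=meta["organ"],
            state=state,
            arch=ArchConfig.from_dict(meta["arch"]),
            preprocess=PreprocessConfig.from_dict(meta["preprocess"]),
            best_val_dsc=meta["best_val_dsc"],
            best_epoch=meta["best_epoch"],
            log=pd.DataFrame(meta["log"]) if meta.get("log") else None,
        )


def predict_volume(net: UNet2D, image: VolumeImage, pcfg: PreprocessConfig) -> np.ndarray:
    """Slice-wise inference: normalize -> crop-free resize -> forward ->
    restore to the native grid; returns a probability volume."""
    out = np.empty(image.grid_shape, dtype=np.float32)
    for k in range(image.grid_shape[2]):
        sl = minmax_normalize(image.data[:, :, k])
        resized, inv = infer_transform(sl, pcfg)
        prob = net.predict_proba(resized[None, None])[0, 0]
        out[:, :, k] = restore_native(np.clip(prob, 0.0, 1.0), inv)
    return out


def _collect_slices(
    subjects: list[PhantomSubject], ids: list[str], organ: str, pcfg: PreprocessConfig
) -> tuple[np.ndarray, np.ndarray]:
    imgs, targets = [], []
    by_id = {s.subject_id: s for s in subjects}
    for sid in ids:
        s = by_id[sid]
        mask = binary_target(s.truth, organ)
        for k in range(s.image.grid_shape[2]):
            sl = minmax_normalize(s.image.data[:, :, k])
            img_t, lab_t = train_transform(sl, mask[:, :, k].astype(np.uint8), pcfg)
            imgs.append(img_t)
            targets.append(lab_t)
    return np.stack(imgs)[:, None], np.stack(targets)[:, None]


def train_organ(
    subjects: list[PhantomSubject],
    split: SplitSpec,
    cfg: TrainConfig,
    log_csv: str | Path | None = None,
) -> OrganCheckpoint:
    """Train one organ's binary network and return the best checkpoint.

    Validation Dice is computed volume-wise on the validation subjects
    after every epoch; the returned checkpoint holds the weights of the
    best epoch and the full per-epoch log (loss and validation Dice).
    """
    train_ids = [s for s in split.subjects("train") if s in {x.subject_id for x in subjects}]
    val_ids = [s for s in split.subjects("val") if s in {x.subject_id for x in subjects}]
    if not train_ids or not val_ids:
        raise ValueError("both train and validation partitions must be non-empty")

    pcfg = cfg.preprocess
    x_train, y_train = _collect_slices(subjects, train_ids, cfg.organ, pcfg)
    by_id = {s.subject_id: s for s in subjects}
    val_subjects = [by_id[sid] for sid in val_ids]
    val_targets = [binary_target(s.truth, cfg.organ) for s in val_subjects]

    arch = ArchConfig(encoder=cfg.encoder, seed=cfg.seed)
    net = build_model(arch)
    opt = Lookahead(
        RAdam(net.parameters(), lr=cfg.lr),
        k=cfg.lookahead_k,
        alpha=cfg.lookahead_alpha,
    )

    rng = np.random.default_rng(cfg.seed)
    n = len(x_train)
    best_state: dict[str, np.ndarray] | None = None
    best_dsc, best_epoch = -1.0, -1
    log_rows = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = x_train[idx]
            yb = y_train[idx]
            if pcfg.augment.enabled:
                aug_seed = int(rng.integers(0, 2**31 - 1))
                xb = xb.copy()
                yb = yb.copy()
                for j in range(len(idx)):
                    xb[j, 0], yb[j, 0] = augment(xb[j, 0], yb[j, 0], pcfg, aug_seed + j)
            logits = net.forward(xb, train=True)
            loss, dz = _loss_and_logit_grad(logits, yb, cfg)
            net.backward(dz.astype(np.float32))
            opt.step(net.gradients())
            epoch_loss += loss
            n_batches += 1

        val_dscs = []
        for s, target in zip(val_subjects, val_targets):
            prob = predict_volume(net, s.image, pcfg)
            val_dscs.append(dsc(prob > 0.5, target))
        val_dsc = float(np.mean(val_dscs))
        log_rows.append({"epoch": epoch, "train_loss": epoch_loss / n_batches, "val_dsc": val_dsc})
        if val_dsc > best_dsc:
            best_dsc, best_epoch = val_dsc, epoch
            best_state = net.state_dict()
        if epoch - best_epoch >= cfg.patience:
            break

    log = pd.DataFrame(log_rows)
    if log_csv is not None:
        log.to_csv(log_csv, index=False)
    assert best_state is not None
    return OrganCheckpoint(
        organ=cfg.organ,
        state=best_state,
        arch=arch,
        preprocess=pcfg,
        best_val_dsc=best_dsc,
        best_epoch=best_epoch,
        log=log,
    )
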