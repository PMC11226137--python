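"""Reading and writing of patch images, annotation masks, manifests and run
configuration.

A patch dataset is laid out as a directory of RGB patch images (PNG/JPEG),
a parallel directory of integer-coded annotation masks (single-channel
paletted PNG), and a CSV manifest assigning each patch to a patient, slide
and cross-validation fold.  Masks code each pixel as background (BG, no
tissue), benign tissue (NC) or one of the Gleason grade patterns G3/G4/G5.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image


class GradeCode(enum.IntEnum):
    """Per-pixel class codes used in annotation masks.

    BG marks non-tissue background (the white slide area), NC benign
    tissue, and G3/G4/G5 the Gleason grade patterns in increasing order of
    aggressiveness.
    """

    BG = 0
    NC = 1
    G3 = 2
    G4 = 3
    G5 = 4


#: The three Gleason grade codes, low to high.
GRADES = (GradeCode.G3, GradeCode.G4, GradeCode.G5)

#: Valid fold names: four validation partitions plus the held-out test set.
FOLDS = ("Val1", "Val2", "Val3", "Val4", "Test")

#: Default mask palette: pixel value equals the GradeCode.
IDENTITY_PALETTE: dict[int, int] = {int(c): int(c) for c in GradeCode}

# Display colours for paletted mask PNGs (BG white, NC pale, grades
# yellow/cyan/orange as commonly used in Gleason annotation figures).
_MASK_COLOURS = {
    GradeCode.BG: (255, 255, 255),
    GradeCode.NC: (190, 210, 190),
    GradeCode.G3: (230, 220, 60),
    GradeCode.G4: (70, 200, 210),
    GradeCode.G5: (240, 140, 40),
}


def read_mask(path: str | Path, palette: Mapping[int, int] | None = None) -> np.ndarray:
    """Read an annotation mask PNG and translate pixel values to GradeCodes.

    Parameters
    ----------
    path
        Single-channel (or paletted) PNG file.
    palette
        Mapping from raw pixel value to GradeCode.  Defaults to the
        identity mapping on codes 0-4.  Every pixel value occurring in the
        file must be mapped.

    Returns
    -------
    ndarray of shape (H, W), dtype uint8, values in GradeCode.
    """
    path = Path(path)
    palette = IDENTITY_PALETTE if palette is None else dict(palette)
    with Image.open(path) as im:
        raw = np.asarray(im.convert("P") if im.mode == "P" else im.convert("L"))
    if raw.size == 0:
        raise ValueError(f"mask {path} has zero size")
    out = np.full(raw.shape, 255, dtype=np.uint8)
    for value, code in palette.items():
        if code not in set(int(c) for c in GradeCode):
            raise ValueError(f"palette maps {value} to invalid code {code}")
        out[raw == value] = code
    unmapped = np.unique(raw[out == 255])
    if unmapped.size:
        raise ValueError(
            f"mask {path} contains pixel value(s) {sorted(int(v) for v in unmapped)} "
            f"not present in the palette"
        )
    return out


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a GradeCode mask as a paletted PNG (pixel value == code)."""
    mask = np.asarray(mask, dtype=np.uint8)
    im = Image.fromarray(mask, mode="P")
    pal = np.zeros((256, 3), dtype=np.uint8)
    for code, rgb in _MASK_COLOURS.items():
        pal[int(code)] = rgb
    im.putpalette(pal.ravel().tolist())
    im.save(Path(path))


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit RGB patch image as PNG."""
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(Path(path))


def read_image(path: str | Path) -> np.ndarray:
    """Read an RGB patch image as an (H, W, 3) uint8 array."""
    with Image.open(Path(path)) as im:
        return np.asarray(im.convert("RGB"))


@dataclasses.dataclass
class PatchRecord:
    """One patch: its image, mask, provenance and slide-space origin."""

    image: np.ndarray
    mask: np.ndarray
    patient_id: str
    slide_id: str
    fold: str
    origin: tuple[int, int]  # (row, col) of top-left pixel, 0-based

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape[:2]:
            raise ValueError("image and mask shapes differ")
        if self.fold not in FOLDS:
            raise ValueError(f"unknown fold {self.fold!r}")


MANIFEST_COLUMNS = ["patch_path", "mask_path", "patient_id", "slide_id", "fold"]


@dataclasses.dataclass
class Manifest:
    """Validated table of patches with patient-exclusive fold assignment."""

    frame: pd.DataFrame
    root: Path | None = None

    def __len__(self) -> int:
        return len(self.frame)

    def resolve(self, relpath: str) -> Path:
        p = Path(relpath)
        return p if p.is_absolute() or self.root is None else self.root / p

    def subset(self, folds: Sequence[str]) -> "Manifest":
        keep = self.frame[self.frame["fold"].isin(list(folds))].reset_index(drop=True)
        return Manifest(keep, root=self.root)


def validate_manifest_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"manifest is missing column(s) {missing}")
    if frame["patch_path"].duplicated().any():
        dupes = frame.loc[frame["patch_path"].duplicated(), "patch_path"].tolist()
        raise ValueError(f"duplicate patch_path entries: {dupes[:5]}")
    bad_folds = set(frame["fold"]) - set(FOLDS)
    if bad_folds:
        raise ValueError(f"unknown fold name(s) {sorted(bad_folds)}; expected {FOLDS}")
    # Patient-exclusive folds: every patient belongs to exactly one fold.
    per_patient = frame.groupby("patient_id")["fold"].nunique()
    offenders = per_patient[per_patient > 1]
    if len(offenders):
        raise ValueError(
            "patient(s) assigned to more than one fold (folds must be "
            f"patient-exclusive): {sorted(offenders.index.tolist())}"
        )
    return frame.reset_index(drop=True)


def load_manifest(path: str | Path, check_paths: bool = False) -> Manifest:
    """Load and validate a patch manifest CSV.

    Columns: ``patch_path,mask_path,patient_id,slide_id,fold`` (an optional
    cached multilabel block ``g3,g4,g5,nc,excluded`` is carried through).
    Relative paths are resolved against the CSV's directory.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"patient_id": str, "slide_id": str})
    frame = validate_manifest_frame(frame)
    man = Manifest(frame, root=path.parent)
    if check_paths:
        for col in ("patch_path", "mask_path"):
            for rel in frame[col]:
                if not man.resolve(rel).exists():
                    raise FileNotFoundError(f"manifest references missing file {rel}")
    return man


def save_manifest(manifest: Manifest, path: str | Path) -> None:
    manifest.frame.to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LabelPolicy:
    """Pixel-fraction rule for turning masks into multi-labels.

    A grade is included in a patch's multi-label when its pixel count
    reaches ``max(min_count, floor(tau * N))`` where N is the denominator
    size: all patch pixels by default (for a 512x512 patch and tau=0.01
    this is 2621 pixels), or only tissue (non-BG) pixels.
    """

    tau: float = 0.01
    denominator: str = "all_pixels"  # or "tissue_pixels"
    min_count: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must be in [0, 1], got {self.tau}")
        if self.denominator not in ("all_pixels", "tissue_pixels"):
            raise ValueError(f"unknown denominator {self.denominator!r}")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")

    def count_threshold(self, denominator_size: int) -> int:
        return max(self.min_count, int(np.floor(self.tau * denominator_size)))


@dataclasses.dataclass
class TrainConfig:
    """Hyperparameters of one one-vs-all sub-classifier.

    Defaults follow the tuned recipe: Adam at base LR 1e-3 dropping by 0.1
    every 15 epochs with a 10x multiplier on the classification head, L2
    1e-2 on conv/FC weights, up to 50 epochs with early stopping after 8
    consecutive epochs of rising validation loss, and resize/rotate/
    translate/flip augmentation.
    """

    base_lr: float = 1e-3
    lr_drop_factor: float = 0.1
    lr_drop_every: int = 15
    head_lr_multiplier: float = 10.0
    max_epochs: int = 50
    early_stop_patience: int = 8
    l2: float = 1e-2
    batch_size: int = 16
    input_size: int = 224
    init: str = "random"  # or "pretrained"
    class_weights: tuple[float, float] | None = None  # (negative, positive)
    augment: bool = True
    rotation_deg: float = 15.0
    translate_frac: float = 0.10
    train_folds: tuple[str, ...] = ("Val1", "Val2", "Val3")
    val_fold: str = "Val4"

    def __post_init__(self) -> None:
        if self.base_lr <= 0:
            raise ValueError(f"base_lr must be positive, got {self.base_lr}")
        if not 0 < self.lr_drop_factor <= 1:
            raise ValueError("lr_drop_factor must be in (0, 1]")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.l2 < 0:
            raise ValueError("l2 must be >= 0")
        if self.class_weights is not None and any(w <= 0 for w in self.class_weights):
            raise ValueError("class weights must be positive")
        if self.init not in ("random", "pretrained"):
            raise ValueError(f"init must be 'random' or 'pretrained', got {self.init!r}")


@dataclasses.dataclass
class RunConfig:
    """Top-level configuration for a full run."""

    label_policy: LabelPolicy = dataclasses.field(default_factory=LabelPolicy)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    ensemble_thresholds: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"G3": 0.5, "G4": 0.5, "G5": 0.5}
    )
    paths: dict[str, str] = dataclasses.field(default_factory=dict)
    mask_palette: dict[int, int] = dataclasses.field(
        default_factory=lambda: dict(IDENTITY_PALETTE)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for g, t in self.ensemble_thresholds.items():
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"ensemble threshold for {g} out of [0,1]: {t}")


def _as_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["train"]["class_weights"] = (
        list(cfg.train.class_weights) if cfg.train.class_weights else None
    )
    d["train"]["train_folds"] = list(cfg.train.train_folds)
    return d


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a RunConfig from a YAML/JSON document, filling defaults.

    An empty or absent document yields the all-defaults configuration
    (tau=0.01, lr=1e-3, L2=1e-2, 50 epochs, patience 8, head LR x10, LR
    drop 0.1 every 15 epochs).  Out-of-range values raise ValueError.
    """
    doc: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if text.strip() else None
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} is not a mapping")
        doc = loaded
    if overrides:
        doc = {**doc, **overrides}

    lp = LabelPolicy(**doc.get("label_policy", {}))
    tr_doc = dict(doc.get("train", {}))
    if tr_doc.get("class_weights") is not None:
        cw = tr_doc["class_weights"]
        tr_doc["class_weights"] = (float(cw[0]), float(cw[1]))
    if "train_folds" in tr_doc:
        tr_doc["train_folds"] = tuple(tr_doc["train_folds"])
    tr = TrainConfig(**tr_doc)
    thresholds = {"G3": 0.5, "G4": 0.5, "G5": 0.5}
    thresholds.update(doc.get("ensemble_thresholds", doc.get("ensemble", {}).get("thresholds", {})
                      if isinstance(doc.get("ensemble"), dict) else {}))
    palette = {int(k): int(v) for k, v in doc.get("mask_palette", IDENTITY_PALETTE).items()}
    return RunConfig(
        label_policy=lp,
        train=tr,
        ensemble_thresholds={k: float(v) for k, v in thresholds.items()},
        paths={str(k): str(v) for k, v in doc.get("paths", {}).items()},
        mask_palette=palette,
        seed=int(doc.get("seed", 0)),
    )


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a RunConfig as YAML; load_config(save_config(c)) == c."""
    Path(path).write_text(yaml.safe_dump(_as_dict(cfg), sort_keys=False))


def config_to_json(cfg: RunConfig) -> str:
    return json.dumps(_as_dict(cfg), sort_keys=True)
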