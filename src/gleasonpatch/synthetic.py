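"""Synthetic histopathology slides, masks and patch datasets.

Generates H&E-like fixtures with the statistical structure the grading
pipeline assumes: a white slide background, a contiguous tissue region of
pale pink benign texture, and Gleason-grade regions (G3/G4/G5) as smooth
random blobs painted with class-distinctive textures — sparse dark
ringlets for G3, dense fused dots for G4 and near-solid dark sheets for
G5.  Per-pixel masks are exactly aligned with the painted regions, patient
identities are assigned exclusively to one of five folds, and slides are
tiled into overlapping patches filtered by an Otsu tissue mask, mirroring
the layout of real patch-level Gleason datasets.

The textures are procedural (smoothed-noise level sets), deterministic in
the seed, and deliberately colour-separated so that class signal survives
aggressive downsampling; they are fixtures for testing the method, not
histologically realistic tissue.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io_formats import (
    FOLDS,
    GRADES,
    GradeCode,
    Manifest,
    PatchRecord,
    save_manifest,
    validate_manifest_frame,
    write_image,
    write_mask,
)

# Per-class procedural texture: flat base colour plus darker "spots" carved
# from a smoothed-noise level set.  density is the spot area fraction,
# scale the smoothing sigma in pixels, ring=True keeps only a band of the
# level set (annular filaments rather than filled dots).
DEFAULT_TEXTURES: dict[GradeCode, dict] = {
    GradeCode.NC: dict(base=(240, 210, 220), spot=(220, 185, 200), density=0.08, scale=2.0, ring=False),
    GradeCode.G3: dict(base=(210, 120, 170), spot=(110, 40, 90), density=0.18, scale=2.0, ring=True),
    GradeCode.G4: dict(base=(130, 90, 180), spot=(70, 40, 110), density=0.35, scale=1.5, ring=False),
    GradeCode.G5: dict(base=(70, 40, 110), spot=(40, 15, 60), density=0.50, scale=3.0, ring=False),
}

_REC601 = np.array([0.299, 0.587, 0.114])


@dataclasses.dataclass
class SyntheticConfig:
    """Parameters of the synthetic slide/patch generator.

    ``class_mixture`` gives per-slide target area fractions of the whole
    slide for NC and each grade; the remainder is white background, so the
    fractions must sum to at most 1.  Patching follows the standard recipe:
    square patches at 50% overlap, dropping windows with less than 20%
    tissue under an Otsu mask.
    """

    n_patients: int = 10
    slides_per_patient: int = 1
    slide_size: tuple[int, int] = (2048, 2048)
    class_mixture: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"NC": 0.45, "G3": 0.09, "G4": 0.09, "G5": 0.09}
    )
    mixture_jitter: float = 0.3
    blob_scale: float = 0.18  # grade-blob smoothing sigma, fraction of slide side
    texture_params: dict = dataclasses.field(default_factory=lambda: DEFAULT_TEXTURES)
    noise_sd: float = 6.0
    patch_size: int = 512
    overlap: float = 0.5
    tissue_min_frac: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_mixture.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"class_mixture sums to {total:.3f} > 1 (remainder must be BG)")
        if any(v < 0 for v in self.class_mixture.values()):
            raise ValueError("class_mixture fractions must be non-negative")
        if self.patch_size < 32:
            raise ValueError("patch_size must be >= 32")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")


_MIX_KEYS = {"NC": GradeCode.NC, "G3": GradeCode.G3, "G4": GradeCode.G4, "G5": GradeCode.G5}


def _top_k_mask(field: np.ndarray, eligible: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k largest field values among eligible pixels."""
    out = np.zeros(field.shape, dtype=bool)
    if k <= 0:
        return out
    vals = field[eligible]
    if k >= vals.size:
        return eligible.copy()
    cutoff = np.partition(vals, vals.size - k)[vals.size - k]
    cand = eligible & (field >= cutoff)
    # resolve ties at the cutoff deterministically in raster order
    extra = int(cand.sum()) - k
    if extra > 0:
        idx = np.flatnonzero(cand.ravel() & (field.ravel() == cutoff))[:extra]
        flat = cand.ravel()
        flat[idx] = False
        cand = flat.reshape(field.shape)
    out |= cand
    return out


def _paint_texture(rgb: np.ndarray, region: np.ndarray, params: Mapping, rng: np.random.Generator) -> None:
    base = np.asarray(params["base"], dtype=float)
    spot = np.asarray(params["spot"], dtype=float)
    rgb[region] = base
    if params["density"] <= 0 or not region.any():
        return
    field = ndimage.gaussian_filter(rng.standard_normal(rgb.shape[:2]), params["scale"])
    if params.get("ring"):
        lo = np.quantile(field, 1.0 - 2.0 * params["density"])
        hi = np.quantile(field, 1.0 - params["density"])
        spots = (field > lo) & (field <= hi)
    else:
        spots = field > np.quantile(field, 1.0 - params["density"])
    rgb[region & spots] = spot


def generate_slide(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Generate one synthetic slide.

    Returns (rgb image HxWx3 uint8, GradeCode mask HxW, ground truth).
    Ground truth has one row per connected region per class with its pixel
    area.  Planted class areas are exact to the pixel: each class occupies
    round(fraction * H * W) pixels, carved from smoothed-noise level sets
    so regions are contiguous blobs.
    """
    h, w = config.slide_size
    n_px = h * w
    targets = {k: int(round(v * n_px)) for k, v in config.class_mixture.items()}
    if sum(targets.values()) > n_px:
        raise ValueError("class mixture infeasible within slide area")

    sigma_t = max(8.0, config.blob_scale * min(h, w) * 2.0)
    tissue_field = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma_t)
    n_tissue = sum(targets.values())
    tissue = _top_k_mask(tissue_field, np.ones((h, w), dtype=bool), n_tissue)

    mask = np.zeros((h, w), dtype=np.uint8)  # BG
    remaining = tissue.copy()
    sigma_g = max(4.0, config.blob_scale * min(h, w))
    # carve the aggressive grades first so each gets its full planted area
    for key in ("G5", "G4", "G3"):
        k = targets.get(key, 0)
        if k == 0:
            continue
        gfield = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma_g)
        region = _top_k_mask(gfield, remaining, k)
        mask[region] = _MIX_KEYS[key]
        remaining &= ~region
    mask[remaining] = GradeCode.NC

    rgb = np.full((h, w, 3), 255.0)
    for code in (GradeCode.NC, GradeCode.G3, GradeCode.G4, GradeCode.G5):
        region = mask == code
        if region.any():
            _paint_texture(rgb, region, config.texture_params[code], rng)
    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=rgb.shape)
        rgb[tissue] += noise[tissue]
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    records = []
    for code in (GradeCode.NC, GradeCode.G3, GradeCode.G4, GradeCode.G5):
        labelled, n_regions = ndimage.label(mask == code)
        for rid in range(1, n_regions + 1):
            records.append(
                {"class": code.name, "region_id": rid, "area_px": int((labelled == rid).sum())}
            )
    return rgb, mask, pd.DataFrame(records, columns=["class", "region_id", "area_px"])


def otsu_tissue_mask(image: np.ndarray) -> np.ndarray:
    """Binary tissue mask by Otsu thresholding of Rec.601 luminance.

    Tissue is the darker class.  A constant image is all background
    (degenerate: no threshold separates anything).
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 3:
        lum = image[..., :3].astype(float) @ _REC601
    else:
        lum = image.astype(float)
    lum = np.clip(np.rint(lum), 0, 255).astype(np.uint8)
    if np.unique(lum).size < 2:
        return np.zeros(lum.shape, dtype=bool)
    t = threshold_otsu(lum)
    return lum <= t


def patch_grid(slide_shape: tuple[int, int], patch_size: int, overlap: float) -> list[tuple[int, int]]:
    """Candidate window origins: half-open windows [r, r+P) x [c, c+P) in
    row-major order at stride P*(1-overlap)."""
    h, w = slide_shape[:2]
    if h < patch_size or w < patch_size:
        raise ValueError(f"slide {h}x{w} smaller than patch size {patch_size}")
    stride = int(round(patch_size * (1.0 - overlap)))
    stride = max(1, stride)
    rows = range(0, h - patch_size + 1, stride)
    cols = range(0, w - patch_size + 1, stride)
    return [(r, c) for r in rows for c in cols]


def extract_patches(
    slide: np.ndarray,
    mask: np.ndarray,
    config: SyntheticConfig,
    patient_id: str = "P00",
    slide_id: str = "S00",
    fold: str = "Test",
) -> list[PatchRecord]:
    """Tile a slide into overlapping patches, keeping tissue-rich windows.

    Windows whose Otsu tissue fraction falls below ``tissue_min_frac``
    are dropped, mirroring the 20%-tissue exclusion rule.
    """
    p = config.patch_size
    records = []
    for r, c in patch_grid(slide.shape[:2], p, config.overlap):
        img = slide[r : r + p, c : c + p]
        tissue_frac = otsu_tissue_mask(img).mean()
        if tissue_frac < config.tissue_min_frac:
            continue
        records.append(
            PatchRecord(
                image=img,
                mask=mask[r : r + p, c : c + p],
                patient_id=patient_id,
                slide_id=slide_id,
                fold=fold,
                origin=(r, c),
            )
        )
    return records


def _jittered_mixture(config: SyntheticConfig, rng: np.random.Generator) -> dict[str, float]:
    """Per-slide mixture variation: grade fractions scaled by a random
    factor, the NC share absorbing the difference (total area preserved)."""
    mix = dict(config.class_mixture)
    if config.mixture_jitter <= 0:
        return mix
    total = sum(mix.values())
    for key in ("G3", "G4", "G5"):
        if key in mix:
            factor = 1.0 + rng.uniform(-config.mixture_jitter, config.mixture_jitter)
            mix[key] = max(0.0, mix[key] * factor)
    mix["NC"] = max(0.0, total - sum(v for k, v in mix.items() if k != "NC"))
    return mix


def generate_dataset(
    config: SyntheticConfig, out_dir: str | Path
) -> tuple[Manifest, pd.DataFrame]:
    """Generate a full patch dataset on disk.

    Patients are assigned round-robin to the five folds (Val1..Val4,
    Test), so every fold sees slides of every mixture profile and class
    presence stays approximately balanced across folds.  Writes
    ``images/``, ``masks/``, ``manifest.csv`` and ``ground_truth.csv``
    under *out_dir* and returns the Manifest plus per-patch ground truth
    (exact per-class pixel counts from the generator's own masks).
    """
    if config.n_patients < len(FOLDS):
        raise ValueError(f"need at least {len(FOLDS)} patients for {len(FOLDS)} folds")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    rows = []
    gt_rows = []
    for p_idx in range(config.n_patients):
        patient = f"P{p_idx:03d}"
        fold = FOLDS[p_idx % len(FOLDS)]
        for s_idx in range(config.slides_per_patient):
            slide_id = f"{patient}_S{s_idx:02d}"
            slide_cfg = dataclasses.replace(config, class_mixture=_jittered_mixture(config, rng))
            slide, mask, _ = generate_slide(slide_cfg, rng)
            for rec in extract_patches(slide, mask, config, patient, slide_id, fold):
                r, c = rec.origin
                stem = f"{slide_id}_r{r}_c{c}"
                img_rel = f"images/{stem}.png"
                mask_rel = f"masks/{stem}.png"
                write_image(rec.image, out_dir / img_rel)
                write_mask(rec.mask, out_dir / mask_rel)
                rows.append(
                    {
                        "patch_path": img_rel,
                        "mask_path": mask_rel,
                        "patient_id": patient,
                        "slide_id": slide_id,
                        "fold": fold,
                    }
                )
                counts = np.bincount(rec.mask.ravel(), minlength=5)
                gt_rows.append(
                    {
                        "patch_path": img_rel,
                        "origin_row": r,
                        "origin_col": c,
                        **{f"n_{code.name.lower()}": int(counts[int(code)]) for code in GradeCode},
                    }
                )

    frame = validate_manifest_frame(pd.DataFrame(rows))
    manifest = Manifest(frame, root=out_dir)
    save_manifest(manifest, out_dir / "manifest.csv")
    gt = pd.DataFrame(gt_rows)
    gt.to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest, gt


def planted_fraction_mask(
    shape: tuple[int, int],
    majority: GradeCode,
    fractions: Mapping[GradeCode, float],
) -> np.ndarray:
    """Mask with exact planted class pixel fractions (of the full mask).

    Each off-majority class receives ``round(fraction * size)`` pixels and
    the majority class the remainder.  Pixels are laid out in raster
    order; spatial arrangement is irrelevant to the counting statistics
    this supports.
    """
    h, w = shape
    size = h * w
    flat = np.full(size, int(majority), dtype=np.uint8)
    pos = 0
    for code, frac in fractions.items():
        if code == majority:
            continue
        k = int(round(frac * size))
        flat[pos : pos + k] = int(code)
        pos += k
    if pos > size:
        raise ValueError("planted fractions exceed mask size")
    return flat.reshape(h, w)
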