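"""Dataset handling: ingestion, preprocessing, and a synthetic cytology generator.

The preprocessing pipeline mirrors common practice for small cytology image
collections: each source image is quartered from its center point (four
quadrant crops), patients — not images — are randomly partitioned 60/20/20
into train/validation/test so no patient's cells leak across splits, and the
training split alone is augmented with 90/180/270-degree rotations.

The synthetic generator draws one cell per image: a light stained background,
an elliptical cytoplasm, and a concentric darker elliptical nucleus.  The two
classes differ in the nucleus-to-cytoplasm area ratio (abnormal cells have a
high N/C ratio) and in nucleus darkness (a hyperchromasia analogue).  Images
from one synthetic patient share style offsets (background tint, cytoplasm
shade), so generalising across patients is a real requirement.  The geometry
is an invented stand-in, not a model of real Papanicolaou-stained cytology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image


@dataclass
class LabeledImage:
    """An RGB image with class label and patient identifier."""

    pixels: np.ndarray  # (H, W, 3) float in [0, 1]
    label: int
    patient_id: str

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) pixels, got {self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.label < 0:
            raise ValueError("label must be a nonnegative class index")


@dataclass
class SplitManifest:
    """Index lists for train/validation/test plus the patient sets behind them."""

    train: List[int]
    val: List[int]
    test: List[int]
    train_patients: List[str]
    val_patients: List[str]
    test_patients: List[str]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    @classmethod
    def from_json(cls, path) -> "SplitManifest":
        return cls(**json.loads(Path(path).read_text()))


class DatasetError(ValueError):
    """Raised with an itemized list of manifest rows that failed to load."""


def load_dataset(manifest_csv, image_root=None) -> List[LabeledImage]:
    """Load images listed in a CSV manifest with columns (path, label, patient_id).

    Images are decoded as RGB (grayscale inputs are replicated to 3 channels)
    and scaled to [0, 1].  All failing rows are reported together.
    """
    df = pd.read_csv(manifest_csv)
    for col in ("path", "label", "patient_id"):
        if col not in df.columns:
            raise DatasetError(f"manifest missing required column {col!r}")
    root = Path(image_root) if image_root else Path(manifest_csv).parent
    images: List[LabeledImage] = []
    errors: List[str] = []
    for _, row in df.iterrows():
        path = root / str(row["path"])
        try:
            label = int(row["label"])
        except (TypeError, ValueError):
            errors.append(f"{path}: unknown label {row['label']!r}")
            continue
        if not path.exists():
            errors.append(f"{path}: file not found")
            continue
        try:
            with Image.open(path) as im:
                arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
        except Exception as exc:  # PIL raises several decode error types
            errors.append(f"{path}: unreadable image ({exc})")
            continue
        images.append(LabeledImage(arr, label, str(row["patient_id"])))
    if errors:
        raise DatasetError("failed to load rows:\n" + "\n".join(errors))
    return images


def write_dataset(images: Sequence[LabeledImage], out_dir) -> Path:
    """Write images as PNGs plus a manifest.csv; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, img in enumerate(images):
        name = f"img_{i:05d}.png"
        arr = np.clip(img.pixels * 255.0 + 0.5, 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(out_dir / name)
        rows.append({"path": name, "label": img.label, "patient_id": img.patient_id})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# ------------------------------------------------------------------ preprocessing


def four_crop(
    image: LabeledImage, size: Optional[Tuple[int, int]] = None, overlap: bool = False
) -> List[LabeledImage]:
    """Crop an image into 4 parts meeting at the center point.

    Default: the four quadrants (floor division; for odd dimensions the center
    row/column is dropped so crops stay equal-sized).  With ``overlap``, four
    half-size crops centered on the image center's four adjacent anchor
    points overlap instead of tiling.  Each crop inherits label and
    patient_id; ``size`` requests a bilinear resize, e.g. (128, 128).
    """
    h, w, _ = image.pixels.shape
    if h < 2 or w < 2:
        raise ValueError(f"image too small to quarter: {h}x{w}")
    hh, hw = h // 2, w // 2
    if overlap:
        qh, qw = max(hh // 2, 1), max(hw // 2, 1)
        anchors = [
            (hh - qh - qh // 2, hw - qw - qw // 2),
            (hh - qh - qh // 2, hw - qw // 2),
            (hh - qh // 2, hw - qw - qw // 2),
            (hh - qh // 2, hw - qw // 2),
        ]
        crops = [
            image.pixels[max(r, 0) : max(r, 0) + 2 * qh, max(c, 0) : max(c, 0) + 2 * qw]
            for r, c in anchors
        ]
    else:
        crops = [
            image.pixels[:hh, :hw],
            image.pixels[:hh, w - hw :],
            image.pixels[h - hh :, :hw],
            image.pixels[h - hh :, w - hw :],
        ]
    out = []
    for crop in crops:
        if size is not None:
            arr = np.clip(crop * 255.0, 0, 255).astype(np.uint8)
            im = Image.fromarray(arr).resize((size[1], size[0]), Image.BILINEAR)
            crop = np.asarray(im, dtype=np.float64) / 255.0
        out.append(LabeledImage(crop.copy(), image.label, image.patient_id))
    return out


def rotation_augment(images: Sequence[LabeledImage]) -> List[LabeledImage]:
    """Originals plus their 90/180/270-degree rotations (4x the input count)."""
    out: List[LabeledImage] = []
    for img in images:
        h, w, _ = img.pixels.shape
        if h != w:
            raise ValueError(f"rotation augmentation needs square images, got {h}x{w}")
        out.append(img)
        for k in (1, 2, 3):
            out.append(
                LabeledImage(np.rot90(img.pixels, k, axes=(0, 1)).copy(), img.label, img.patient_id)
            )
    return out


def patient_split(
    samples: Sequence[LabeledImage],
    fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitManifest:
    """Partition samples 60/20/20 by patient, never splitting a patient.

    Patients are shuffled by a seeded RNG and allocated floor(0.6 P) /
    floor(0.2 P) / remainder; every sample follows its patient.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    patients = sorted({s.patient_id for s in samples})
    if len(patients) < 3:
        raise ValueError("need at least 3 distinct patients to split")
    rng = np.random.default_rng(seed)
    patients = list(rng.permutation(patients))
    p = len(patients)
    n_train = int(np.floor(fractions[0] * p))
    n_val = int(np.floor(fractions[1] * p))
    train_p = set(patients[:n_train])
    val_p = set(patients[n_train : n_train + n_val])
    test_p = set(patients[n_train + n_val :])
    train, val, test = [], [], []
    for i, s in enumerate(samples):
        if s.patient_id in train_p:
            train.append(i)
        elif s.patient_id in val_p:
            val.append(i)
        else:
            test.append(i)
    return SplitManifest(
        train, val, test, sorted(train_p), sorted(val_p), sorted(test_p)
    )


# ------------------------------------------------------------- synthetic generator


@dataclass(frozen=True)
class SynthParams:
    """Conditions for the synthetic cytology generator.

    The class contrast follows urinary-cytology grading practice: abnormal
    cells have a nucleus-to-cytoplasm area ratio above 0.5 and darker
    (hyperchromatic) nuclei; normal cells have a low N/C ratio and paler
    nuclei.  Defaults give a moderately hard task: heavy pixel noise and
    per-patient style offsets prevent trivial separation.
    """

    n_patients: int = 40
    images_per_patient: int = 20
    abnormal_fraction: float = 0.5
    nc_ratio_normal: Tuple[float, float] = (0.15, 0.35)
    nc_ratio_abnormal: Tuple[float, float] = (0.55, 0.80)
    nucleus_intensity_normal: Tuple[float, float] = (0.25, 0.45)
    nucleus_intensity_abnormal: Tuple[float, float] = (0.12, 0.38)
    noise_sd: float = 0.25
    image_size: int = 32
    seed: int = 0

    def __post_init__(self):
        for rng_ in (self.nc_ratio_normal, self.nc_ratio_abnormal):
            if not (0 < rng_[0] < rng_[1] < 1):
                raise ValueError(f"N/C ratio range must be within (0,1): {rng_}")
        if self.nc_ratio_abnormal[0] <= self.nc_ratio_normal[1]:
            raise ValueError(
                "abnormal N/C ratio range must lie strictly above the normal range"
            )
        if not 0 < self.abnormal_fraction < 1:
            raise ValueError("abnormal_fraction must be in (0,1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_patients < 1 or self.images_per_patient < 1:
            raise ValueError("counts must be positive")


def _ellipse_mask(size: int, cy: float, cx: float, ay: float, ax: float, theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    y = yy - cy
    x = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / ax) ** 2 + (v / ay) ** 2 <= 1.0


def generate_synthetic_dataset(
    params: SynthParams, return_masks: bool = False
) -> List[LabeledImage] | Tuple[List[LabeledImage], List[Dict]]:
    """Generate a synthetic cytology dataset (deterministic given the seed).

    Each image contains one cell: elliptical cytoplasm plus a concentric
    nucleus whose area is a class-dependent fraction of the cell area.
    Patients carry shared style offsets.  With ``return_masks`` the per-image
    drawn geometry (pixel areas of nucleus and cell, drawn ratio) is returned
    alongside, so tests can re-measure the N/C ratio from the masks.
    """
    rng = np.random.default_rng(params.seed)
    s = params.image_size
    images: List[LabeledImage] = []
    meta: List[Dict] = []
    for p in range(params.n_patients):
        pid = f"patient_{p:03d}"
        bg = rng.uniform(0.80, 0.92)
        tint = rng.uniform(-0.05, 0.05, size=3)
        cyto_base = np.array(
            [rng.uniform(0.55, 0.70), rng.uniform(0.60, 0.75), rng.uniform(0.65, 0.80)]
        )
        for _ in range(params.images_per_patient):
            label = int(rng.random() < params.abnormal_fraction)
            ratio_rng = params.nc_ratio_abnormal if label else params.nc_ratio_normal
            nuc_rng = (
                params.nucleus_intensity_abnormal
                if label
                else params.nucleus_intensity_normal
            )
            ratio = rng.uniform(*ratio_rng)
            nuc_int = rng.uniform(*nuc_rng)

            # cell ellipse centered near the image center
            cy = s / 2 + rng.uniform(-0.05, 0.05) * s
            cx = s / 2 + rng.uniform(-0.05, 0.05) * s
            area_frac = rng.uniform(0.22, 0.40)
            ecc = rng.uniform(0.7, 1.0)
            a = np.sqrt(area_frac * s * s / (np.pi * ecc))
            ay, ax_ = a * ecc, a
            theta = rng.uniform(0, np.pi)
            cell = _ellipse_mask(s, cy, cx, ay, ax_, theta)

            # nucleus: same shape scaled by sqrt(ratio), small inside offset
            scale = np.sqrt(ratio)
            max_off = 0.5 * (1 - scale) * min(ay, ax_)
            ncy = cy + rng.uniform(-max_off, max_off)
            ncx = cx + rng.uniform(-max_off, max_off)
            nucleus = _ellipse_mask(s, ncy, ncx, ay * scale, ax_ * scale, theta)
            nucleus &= cell

            img = np.empty((s, s, 3))
            img[...] = np.clip(bg + tint, 0, 1)
            cyto_col = np.clip(cyto_base + rng.uniform(-0.04, 0.04, 3), 0, 1)
            img[cell] = cyto_col
            nuc_col = np.clip(
                np.array([nuc_int * 0.9, nuc_int * 0.8, nuc_int * 1.1])
                + rng.uniform(-0.03, 0.03, 3),
                0,
                1,
            )
            img[nucleus] = nuc_col
            img += rng.normal(0.0, params.noise_sd, size=img.shape)
            np.clip(img, 0.0, 1.0, out=img)
            images.append(LabeledImage(img, label, pid))
            meta.append(
                {
                    "drawn_ratio": float(ratio),
                    "nucleus_area": int(nucleus.sum()),
                    "cell_area": int(cell.sum()),
                    "nucleus_intensity": float(nuc_int),
                }
            )
    if return_masks:
        return images, meta
    return images


# -------------------------------------------------------------------- pipeline


def prepare_splits(
    images: Sequence[LabeledImage],
    seed: int = 0,
    crop_size: Optional[Tuple[int, int]] = None,
    fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2),
    augment_train: bool = True,
) -> Dict[str, List[LabeledImage]]:
    """Full preprocessing: 4-crop everything, patient split, augment train only."""
    manifest = patient_split(images, fractions=fractions, seed=seed)
    out: Dict[str, List[LabeledImage]] = {}
    for name, idxs in (("train", manifest.train), ("val", manifest.val), ("test", manifest.test)):
        crops: List[LabeledImage] = []
        for i in idxs:
            crops.extend(four_crop(images[i], size=crop_size))
        out[name] = crops
    if augment_train:
        out["train"] = rotation_augment(out["train"])
    out["manifest"] = manifest
    return out


def to_arrays(images: Sequence[LabeledImage]) -> Tuple[np.ndarray, np.ndarray]:
    """Stack a list of equally sized LabeledImages into (X, y) arrays."""
    X = np.stack([img.pixels for img in images])
    y = np.array([img.label for img in images], dtype=int)
    return X, y
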