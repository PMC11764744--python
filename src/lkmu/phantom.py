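"""Synthetic OCT B-scan phantoms with per-pixel fluid labels.

The generator emulates the gross appearance of retinal OCT: a stack of
curved reflective bands (retinal layers) over a darker background,
hypo-reflective fluid pockets of varying shape and size, Gaussian edge
blur and multiplicative gamma-distributed speckle.  Three device profiles
(A/B/C) rescale contrast and speckle to mimic multi-vendor variation.
Class semantics mirror the three fluid types of multi-class OCT grading:
class 1 — rounded intraretinal pockets; class 2 — lens-shaped pockets
under a layer boundary; class 3 — dome-shaped detachments on the bottom
band.  No claim of clinical realism is made; the phantoms exist so the
entire pipeline is exercisable without external data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.filters import gaussian as _gaussian_blur

__all__ = [
    "PhantomSpec",
    "Sample",
    "generate_phantom",
    "generate_dataset",
    "split_dataset",
    "augment",
    "normalize",
    "denormalize",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "DEVICE_PROFILES",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

# contrast scale and speckle-shape scale per emulated device; smaller
# speckle shape = heavier multiplicative noise, so C is noisiest
DEVICE_PROFILES = {
    "A": {"contrast": 1.00, "speckle": 1.00},
    "B": {"contrast": 0.85, "speckle": 0.60},
    "C": {"contrast": 0.70, "speckle": 0.35},
}


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 256
    width: int = 256
    n_layers: int = 8
    layer_intensity_range: tuple = (0.2, 0.8)
    curvature_amplitude: float = 8.0
    speckle_shape: float = 60.0
    n_classes: int = 1
    blobs_per_class: tuple = (1, 3)
    axis_range: tuple = (4, 60)
    intensity_drop: float = 0.35
    edge_blur_sigma: float = 1.0
    device_profile: str = "A"

    def __post_init__(self):
        if self.height < 32 or self.width < 32:
            raise ValueError("phantoms must be at least 32x32")
        if not 6 <= self.n_layers <= 10:
            raise ValueError("n_layers must lie in [6, 10]")
        if self.n_classes not in (1, 3):
            raise ValueError("n_classes must be 1 or 3")
        if not 0.0 < self.intensity_drop < 1.0:
            raise ValueError("intensity_drop must lie in (0, 1)")
        lo, hi = self.blobs_per_class
        if lo < 0 or hi < lo:
            raise ValueError("invalid blobs_per_class range")
        lo, hi = self.axis_range
        if lo < 2 or hi < lo:
            raise ValueError("invalid axis_range")
        if self.device_profile not in DEVICE_PROFILES:
            raise ValueError(f"device_profile must be one of "
                             f"{sorted(DEVICE_PROFILES)}")
        if self.speckle_shape <= 1.0:
            raise ValueError("speckle_shape must exceed 1")

    def to_dict(self):
        import dataclasses
        d = dataclasses.asdict(self)
        d["layer_intensity_range"] = list(self.layer_intensity_range)
        d["blobs_per_class"] = list(self.blobs_per_class)
        d["axis_range"] = list(self.axis_range)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        for key in ("layer_intensity_range", "blobs_per_class", "axis_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclass
class Sample:
    image: np.ndarray  # (H, W) float32 in [0, 1]
    mask: np.ndarray   # (H, W) uint8 labels 0..n_classes
    meta: dict = field(default_factory=dict)


def _deformed_ellipse(rows, cols, center, axes, angle, rng):
    """Boolean mask of an ellipse with a low-frequency radial perturbation."""
    cy, cx = center
    ay, ax = axes
    dy = rows - cy
    dx = cols - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / ax
    v = (-sa * dx + ca * dy) / ay
    rho = np.sqrt(u * u + v * v)
    theta = np.arctan2(v, u)
    wobble = np.zeros_like(theta)
    for k in (2, 3):
        wobble += rng.uniform(0.0, 0.12) * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    return rho < 1.0 + wobble


def generate_phantom(spec: PhantomSpec, seed: int) -> Sample:
    """Deterministically renders one phantom B-scan and its label mask."""
    rng = np.random.default_rng(seed)
    H, W = spec.height, spec.width
    profile = DEVICE_PROFILES[spec.device_profile]
    cols = np.arange(W, dtype=np.float64)
    rows = np.arange(H, dtype=np.float64)[:, None]
    cgrid = np.broadcast_to(cols[None, :], (H, W))
    rgrid = np.broadcast_to(rows, (H, W))

    # -- curved layer boundaries -------------------------------------
    curvature = (spec.curvature_amplitude
                 * np.sin(2 * np.pi * cols / W * rng.uniform(0.5, 1.5)
                          + rng.uniform(0, 2 * np.pi)))
    top = rng.uniform(0.18, 0.30) * H
    bottom = rng.uniform(0.68, 0.80) * H
    widths = rng.uniform(0.5, 1.5, size=spec.n_layers)
    widths /= widths.sum()
    bounds = top + np.concatenate(([0.0], np.cumsum(widths))) * (bottom - top)
    boundary_rows = bounds[:, None] + curvature[None, :]  # (n_layers+1, W)

    # -- band intensities (ascending with depth, bright outer bands) --
    lo, hi = spec.layer_intensity_range
    intensities = np.sort(rng.uniform(lo, hi, size=spec.n_layers))
    image = np.full((H, W), 0.05, dtype=np.float64)
    image += 0.02 * rng.standard_normal((H, W))  # faint background texture
    for b in range(spec.n_layers):
        band = (rgrid >= boundary_rows[b][None, :]) & \
               (rgrid < boundary_rows[b + 1][None, :])
        image[band] = intensities[b]
    below = rgrid >= boundary_rows[-1][None, :]
    image[below] = 0.15
    band_region = (rgrid >= boundary_rows[0][None, :]) & ~below

    # -- fluid regions -------------------------------------------------
    mask = np.zeros((H, W), dtype=np.uint8)
    inventory = []
    amin, amax = spec.axis_range
    amax_eff = min(amax, H // 4, W // 4)
    retina_thickness = bottom - top
    for cls in range(1, spec.n_classes + 1):
        n_blobs = int(rng.integers(spec.blobs_per_class[0],
                                   spec.blobs_per_class[1] + 1))
        for _ in range(n_blobs):
            ay = rng.uniform(amin, max(amin + 1, amax_eff))
            ax = rng.uniform(amin, max(amin + 1, amax_eff))
            cx = rng.uniform(0.1 * W, 0.9 * W)
            if cls == 1:
                cy = rng.uniform(top + 0.15 * retina_thickness,
                                 bottom - 0.15 * retina_thickness)
                angle = rng.uniform(0, np.pi)
                blob = _deformed_ellipse(rgrid, cgrid, (cy, cx), (ay, ax),
                                         angle, rng)
            elif cls == 2:
                # lens-shaped pocket hanging under an internal boundary
                b = int(rng.integers(1, spec.n_layers))
                cy_line = bounds[b]
                blob = _deformed_ellipse(rgrid, cgrid, (cy_line, cx),
                                         (ay, 1.6 * ax), 0.0, rng)
                blob &= rgrid >= (boundary_rows[b][None, :])
                cy = cy_line
            else:
                # dome-shaped bump sitting on the bottom band
                cy_line = bounds[-1]
                blob = _deformed_ellipse(rgrid, cgrid, (cy_line, cx),
                                         (1.3 * ay, 1.6 * ax), 0.0, rng)
                blob &= rgrid <= (boundary_rows[-1][None, :])
                cy = cy_line
            blob &= band_region
            if not blob.any():
                continue
            image[blob] *= (1.0 - spec.intensity_drop)
            mask[blob] = cls
            inventory.append({
                "cls": cls, "cy": float(cy), "cx": float(cx),
                "ay": float(ay), "ax": float(ax),
                "pixels": int(blob.sum()),
            })

    # -- contrast, blur, speckle --------------------------------------
    image = 0.5 + profile["contrast"] * (image - 0.5)
    image = _gaussian_blur(image, sigma=spec.edge_blur_sigma,
                           preserve_range=True)
    k = spec.speckle_shape * profile["speckle"]
    image *= rng.gamma(shape=k, scale=1.0 / k, size=(H, W))
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    meta = {
        "seed": int(seed),
        "spec_digest": spec.digest(),
        "device_profile": spec.device_profile,
        "blobs": inventory,
    }
    return Sample(image=image, mask=mask, meta=meta)


# ---------------------------------------------------------------------------
# dataset IO
# ---------------------------------------------------------------------------

def generate_dataset(spec: PhantomSpec, n: int, seed: int, out_dir) -> pd.DataFrame:
    """Writes ``n`` phantom image/mask PNG pairs plus a manifest CSV.

    Images are 8-bit grayscale PNGs; masks are 8-bit PNGs holding the
    literal label values 0..n_classes.  Returns the manifest DataFrame
    (also written to ``out_dir/manifest.csv``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        sample_seed = int((seed * 100003 + i) % (2 ** 31 - 1))
        sample = generate_phantom(spec, sample_seed)
        img_name = f"phantom_{i:04d}.png"
        mask_name = f"phantom_{i:04d}_mask.png"
        img8 = np.round(sample.image * 255).astype(np.uint8)
        Image.fromarray(img8, mode="L").save(out_dir / img_name)
        Image.fromarray(sample.mask, mode="L").save(out_dir / mask_name)
        row = {
            "image": img_name,
            "mask": mask_name,
            "seed": sample_seed,
            "device_profile": spec.device_profile,
        }
        for c in range(1, spec.n_classes + 1):
            row[f"pixels_class_{c}"] = int(np.sum(sample.mask == c))
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_manifest(path):
    path = Path(path)
    df = pd.read_csv(path)
    df.attrs["root"] = str(path.parent)
    return df


def load_sample(manifest_row, root) -> Sample:
    root = Path(root)
    image = np.asarray(Image.open(root / manifest_row["image"]).convert("L"),
                       dtype=np.float32) / 255.0
    mask = np.asarray(Image.open(root / manifest_row["mask"]),
                      dtype=np.uint8)
    return Sample(image=image, mask=mask,
                  meta={"image": manifest_row["image"]})


def split_dataset(manifest: pd.DataFrame, ratios=(8, 1, 1), seed: int = 0):
    """Random disjoint train/val/test split.

    Validation and test sizes are floor-allocated from the ratios; the
    remainder goes to training (100 samples at 8:1:1 -> 80/10/10).
    """
    if any(r <= 0 for r in ratios) or len(ratios) != 3:
        raise ValueError("ratios must be three positive numbers")
    n = len(manifest)
    total = sum(ratios)
    n_val = int(n * ratios[1] / total)
    n_test = int(n * ratios[2] / total)
    order = np.random.default_rng(seed).permutation(n)
    val_idx = order[:n_val]
    test_idx = order[n_val:n_val + n_test]
    train_idx = order[n_val + n_test:]
    parts = tuple(
        manifest.iloc[np.sort(idx)].reset_index(drop=True)
        for idx in (train_idx, val_idx, test_idx)
    )
    for part in parts:
        part.attrs["root"] = manifest.attrs.get("root", "")
    return parts


# ---------------------------------------------------------------------------
# augmentation / normalization
# ---------------------------------------------------------------------------

def augment(sample: Sample, seed: int, hflip=None, vflip=None,
            angle=None) -> Sample:
    """Random horizontal/vertical flips (p = 0.5 each) and a rotation
    uniform in [-15, +15] degrees; image and mask transform identically
    (nearest-neighbour for the mask).  Any of ``hflip``/``vflip``/
    ``angle`` may be forced for reproducible tests."""
    rng = np.random.default_rng(seed)
    if hflip is None:
        hflip = bool(rng.random() < 0.5)
    if vflip is None:
        vflip = bool(rng.random() < 0.5)
    if angle is None:
        angle = float(rng.uniform(-15.0, 15.0))
    image = sample.image.copy()
    mask = sample.mask.copy()
    if hflip:
        image = image[:, ::-1]
        mask = mask[:, ::-1]
    if vflip:
        image = image[::-1, :]
        mask = mask[::-1, :]
    if angle != 0.0:
        image = ndimage.rotate(image, angle, reshape=False, order=1,
                               mode="constant", cval=0.0)
        mask = ndimage.rotate(mask, angle, reshape=False, order=0,
                              mode="constant", cval=0)
    meta = dict(sample.meta)
    meta["augment"] = {"hflip": hflip, "vflip": vflip, "angle": angle}
    return Sample(image=np.ascontiguousarray(np.clip(image, 0.0, 1.0),
                                             dtype=np.float32),
                  mask=np.ascontiguousarray(mask, dtype=np.uint8),
                  meta=meta)


def normalize(image, mean=IMAGENET_MEAN, std=IMAGENET_STD) -> np.ndarray:
    """Grayscale (H, W) in [0, 1] -> ImageNet-normalized (3, H, W)."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError("normalize expects a single-channel (H, W) image")
    rep = np.repeat(image[None], 3, axis=0)
    return (rep - mean[:, None, None]) / std[:, None, None]


def denormalize(channels, mean=IMAGENET_MEAN, std=IMAGENET_STD) -> np.ndarray:
    """Inverse of :func:`normalize`; returns the grayscale (H, W) image."""
    channels = np.asarray(channels, dtype=np.float32)
    rep = channels * std[:, None, None] + mean[:, None, None]
    return rep.mean(axis=0)
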