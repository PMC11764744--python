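"""Training loop, checkpointing, evaluation and batch prediction.

Protocol: Adam (lr 1e-3, weight decay 1e-4), batch size 8, 150 epochs,
polynomial learning-rate decay with power 0.9, composite 0.5*BCE + Dice
objective, ImageNet-statistics normalization of the grayscale input
replicated to three channels, random flip/rotation augmentation of the
training split only.  The checkpoint with the lowest validation loss is
kept.  Everything is seeded and single-process, so two runs with the same
configuration produce identical logs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy.special import expit

from .losses import composite_loss_logits, poly_lr
from .metrics import METRIC_NAMES, seg_metrics
from .network import ArchConfig, LKMULite, build_model, mask_from_probs
from .nn import Adam
from .nn import autograd as ag
from .phantom import augment, load_manifest, load_sample, normalize

__all__ = ["TrainConfig", "train", "evaluate", "predict",
           "save_checkpoint", "load_checkpoint", "fit_arrays"]

# class colour key for overlays: 1 red, 2 yellow, 3 blue
OVERLAY_PALETTE = {1: (255, 0, 0), 2: (255, 255, 0), 3: (0, 0, 255)}


@dataclass
class TrainConfig:
    arch: ArchConfig = field(default_factory=ArchConfig)
    epochs: int = 150
    batch_size: int = 8
    lr: float = 1e-3
    weight_decay: float = 1e-4
    lr_power: float = 0.9
    seed: int = 0
    augment: bool = True
    threshold: float = 0.5
    stop_train_dsc: float | None = None
    train_manifest: str | None = None
    val_manifest: str | None = None
    out_dir: str = "runs/lkmu"

    def __post_init__(self):
        if isinstance(self.arch, dict):
            self.arch = ArchConfig.from_dict(self.arch)
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.lr <= 0 or self.weight_decay < 0 or self.lr_power <= 0:
            raise ValueError("invalid optimizer hyperparameters")

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["arch"] = self.arch.to_dict()
        return d

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: LKMULite, path, extra=None):
    """Writes weights (npz) plus a JSON sidecar with the architecture so
    the model is rebuildable without code inspection."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = {"arch": model.cfg.to_dict(), **(extra or {})}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path):
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    cfg = ArchConfig.from_dict(sidecar["arch"])
    model = LKMULite(cfg)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    model.eval()
    return model, sidecar


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def _to_target(mask, num_classes):
    """Label mask (H, W) -> one-hot foreground target (C, H, W)."""
    return np.stack([(mask == c).astype(np.float32)
                     for c in range(1, num_classes + 1)])


def _check_size(image, where):
    h, w = image.shape[-2:]
    if h % 16 or w % 16:
        raise ValueError(
            f"{where}: image size {h}x{w} is not divisible by 16; resize or "
            f"pad before training")


def _load_split(manifest, root):
    samples = [load_sample(row, root) for _, row in manifest.iterrows()]
    if not samples:
        raise ValueError("empty manifest")
    for s in samples:
        _check_size(s.image, "data loading")
    return samples


def _forward_probs(model, images_norm, batch_size=8):
    """Eval-mode per-class probabilities for a stack of normalized images."""
    model.eval()
    probs = []
    with ag.no_grad():
        for i in range(0, len(images_norm), batch_size):
            logits = model(np.stack(images_norm[i:i + batch_size])).data
            probs.append(expit(logits.astype(np.float64)))
    return np.concatenate(probs, axis=0)


def _mean_dsc(model, images_norm, masks, num_classes, threshold, batch_size=8):
    probs = _forward_probs(model, images_norm, batch_size)
    scores = []
    for p, gt in zip(probs, masks):
        pred = mask_from_probs(p, threshold)
        rep = seg_metrics(pred, gt, n_classes=num_classes, compute_hd95=False)
        scores.append(rep.mean["dsc"])
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# core fitting loop
# ---------------------------------------------------------------------------

def fit_arrays(model, train_samples, val_samples, *, epochs, batch_size,
               lr, weight_decay, lr_power, seed, augment_train=True,
               threshold=0.5, stop_train_dsc=None, on_epoch_end=None):
    """Trains ``model`` in place on in-memory samples; returns the log as a
    DataFrame plus the best (lowest validation loss) state dict.

    ``stop_train_dsc`` enables the capacity-check mode: after each epoch the
    mean training DSC is measured in evaluation mode and training stops as
    soon as it reaches the target.
    """
    rng = np.random.default_rng(seed)
    num_classes = model.cfg.num_classes
    opt = Adam(model.parameters(), lr=lr, weight_decay=weight_decay)

    val_images = [normalize(s.image) for s in val_samples]
    val_targets = np.stack([_to_target(s.mask, num_classes)
                            for s in val_samples])
    plain_train_images = [normalize(s.image) for s in train_samples]
    train_masks = [s.mask for s in train_samples]

    rows = []
    best = {"epoch": -1, "val_loss": np.inf, "state": None}
    for epoch in range(epochs):
        lr_epoch = poly_lr(epoch, initial_lr=lr, num_epochs=epochs,
                           power=lr_power)
        opt.lr = lr_epoch
        if augment_train:
            epoch_samples = [augment(s, int(rng.integers(2 ** 31 - 1)))
                             for s in train_samples]
        else:
            epoch_samples = train_samples
        order = rng.permutation(len(epoch_samples))
        model.train()
        losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            x = np.stack([normalize(epoch_samples[i].image) for i in idx])
            t = np.stack([_to_target(epoch_samples[i].mask, num_classes)
                          for i in idx])
            opt.zero_grad()
            loss = composite_loss_logits(model(x), t)
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(idx))
        train_loss = float(np.sum(losses) / len(order))

        model.eval()
        with ag.no_grad():
            val_losses = []
            for i in range(0, len(val_images), batch_size):
                x = np.stack(val_images[i:i + batch_size])
                t = val_targets[i:i + batch_size]
                val_losses.append(
                    float(composite_loss_logits(model(x), t).data) * len(x))
            val_loss = float(np.sum(val_losses) / len(val_images))

        row = {"epoch": epoch, "lr": lr_epoch,
               "train_loss": train_loss, "val_loss": val_loss}
        if stop_train_dsc is not None:
            row["train_dsc"] = _mean_dsc(model, plain_train_images,
                                         train_masks, num_classes, threshold,
                                         batch_size)
        rows.append(row)
        if val_loss < best["val_loss"]:
            best = {"epoch": epoch, "val_loss": val_loss,
                    "state": model.state_dict()}
        if on_epoch_end is not None:
            on_epoch_end(row)
        if stop_train_dsc is not None and row["train_dsc"] >= stop_train_dsc:
            break
    return pd.DataFrame(rows), best


def train(cfg: TrainConfig):
    """File-based training entry point.

    Reads the train/val manifests, runs :func:`fit_arrays`, writes
    ``log.csv``, ``best.npz`` (+ JSON sidecar) and ``last.npz`` under
    ``cfg.out_dir`` and returns a result dict.
    """
    if not cfg.train_manifest or not cfg.val_manifest:
        raise ValueError("train_manifest and val_manifest are required")
    train_manifest = load_manifest(cfg.train_manifest)
    val_manifest = load_manifest(cfg.val_manifest)
    train_samples = _load_split(train_manifest, train_manifest.attrs["root"])
    val_samples = _load_split(val_manifest, val_manifest.attrs["root"])

    model = build_model(cfg.arch, seed=cfg.seed)
    log, best = fit_arrays(
        model, train_samples, val_samples,
        epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.lr,
        weight_decay=cfg.weight_decay, lr_power=cfg.lr_power, seed=cfg.seed,
        augment_train=cfg.augment, threshold=cfg.threshold,
        stop_train_dsc=cfg.stop_train_dsc)

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.to_csv(out_dir / "log.csv", index=False)
    save_checkpoint(model, out_dir / "last.npz",
                    extra={"epoch": int(log["epoch"].iloc[-1])})
    last_state = model.state_dict()
    model.load_state_dict(best["state"])
    save_checkpoint(model, out_dir / "best.npz",
                    extra={"epoch": best["epoch"],
                           "val_loss": best["val_loss"]})
    model.load_state_dict(last_state)
    return {
        "log": log,
        "best_epoch": best["epoch"],
        "best_val_loss": best["val_loss"],
        "best_checkpoint": str(out_dir / "best.npz"),
        "last_checkpoint": str(out_dir / "last.npz"),
        "model": model,
    }


# ---------------------------------------------------------------------------
# evaluation / prediction
# ---------------------------------------------------------------------------

def evaluate(checkpoint, manifest, out_csv=None, threshold=0.5,
             batch_size=8) -> pd.DataFrame:
    """Per-sample, per-class metrics on a manifest; deterministic.

    ``checkpoint`` is a path to a saved model or an already-loaded
    :class:`LKMULite`.  Rows: one per (sample, class), one "mean" row per
    sample (arithmetic mean over its class rows), and final aggregate
    rows per class and overall.
    """
    if isinstance(checkpoint, LKMULite):
        model = checkpoint
    else:
        model, _ = load_checkpoint(checkpoint)
    manifest = (load_manifest(manifest) if not isinstance(manifest, pd.DataFrame)
                else manifest)
    samples = _load_split(manifest, manifest.attrs.get("root", "."))
    num_classes = model.cfg.num_classes
    max_label = int(max(s.mask.max(initial=0) for s in samples))
    if max_label > num_classes:
        raise ValueError(
            f"checkpoint predicts {num_classes} classes but the data holds "
            f"labels up to {max_label}")
    images = [normalize(s.image) for s in samples]
    probs = _forward_probs(model, images, batch_size)
    rows = []
    for i, (p, s) in enumerate(zip(probs, samples)):
        pred = mask_from_probs(p, threshold)
        rep = seg_metrics(pred, s.mask, n_classes=num_classes)
        name = s.meta.get("image", f"sample_{i}")
        for c, scores in rep.per_class.items():
            rows.append({"sample": name, "class": str(c), **scores})
        rows.append({"sample": name, "class": "mean", **rep.mean})
    df = pd.DataFrame(rows)
    per_sample = df[df["class"] != "mean"]
    for c in sorted(per_sample["class"].unique()):
        sub = per_sample[per_sample["class"] == c]
        rows.append({"sample": "ALL", "class": c,
                     **{m: float(sub[m].mean()) for m in METRIC_NAMES}})
    rows.append({"sample": "ALL", "class": "mean",
                 **{m: float(per_sample[m].mean()) for m in METRIC_NAMES}})
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


def predict(checkpoint, image_paths, out_dir, threshold=0.5):
    """Predicts label masks for image files; writes ``<stem>_mask.png`` and
    an RGB ``<stem>_overlay.png`` (class 1 red, 2 yellow, 3 blue) per
    readable input.  Raises if every input fails."""
    if isinstance(checkpoint, LKMULite):
        model = checkpoint
    else:
        model, _ = load_checkpoint(checkpoint)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for path in image_paths:
        path = Path(path)
        try:
            gray = np.asarray(Image.open(path).convert("L"),
                              dtype=np.float32) / 255.0
            _check_size(gray, str(path))
        except Exception as exc:  # noqa: BLE001 - per-file warning by contract
            warnings.warn(f"skipping {path}: {exc}", stacklevel=2)
            continue
        with ag.no_grad():
            logits = model(normalize(gray)[None]).data[0]
        probs = expit(logits.astype(np.float64))
        mask = mask_from_probs(probs, threshold)
        overlay = np.repeat(np.round(gray * 255).astype(np.uint8)[..., None],
                            3, axis=2)
        for c, colour in OVERLAY_PALETTE.items():
            overlay[mask == c] = colour
        mask_path = out_dir / f"{path.stem}_mask.png"
        overlay_path = out_dir / f"{path.stem}_overlay.png"
        Image.fromarray(mask, mode="L").save(mask_path)
        Image.fromarray(overlay, mode="RGB").save(overlay_path)
        written.append((str(mask_path), str(overlay_path)))
    if not written:
        raise RuntimeError("no input image could be processed")
    return written
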