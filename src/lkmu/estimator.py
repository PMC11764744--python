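"""scikit-learn style estimator facade over the segmentation pipeline.

``LKMULiteSegmenter`` wraps model construction, training and mask
prediction behind the familiar fit/predict surface so the network can sit
inside sklearn model-selection utilities.  Inputs are stacks of grayscale
images in [0, 1] shaped (n, H, W) with integer label masks of the same
shape as targets.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .network import ArchConfig, build_model, mask_from_probs
from .phantom import Sample, normalize
from .train import _forward_probs, fit_arrays
from .metrics import seg_metrics

__all__ = ["LKMULiteSegmenter"]


class LKMULiteSegmenter(BaseEstimator):
    """U-shaped retinal-fluid segmenter with large-kernel attention.

    Parameters mirror the training protocol: Adam with polynomially
    decaying learning rate and the composite 0.5*BCE + Dice objective.

    Attributes (after ``fit``)
    --------------------------
    model_ : the trained network
    history_ : per-epoch DataFrame (lr, train/val loss)
    best_epoch_ : epoch index with the lowest validation loss
    """

    def __init__(self, num_classes=1, stage_channels=(32, 64, 128, 160, 256),
                 dwd_kernel=7, decoder_variant="aggshift", epochs=20,
                 batch_size=8, lr=1e-3, weight_decay=1e-4, lr_power=0.9,
                 augment=False, threshold=0.5, stop_train_dsc=None,
                 validation_fraction=0.0, seed=0):
        self.num_classes = num_classes
        self.stage_channels = stage_channels
        self.dwd_kernel = dwd_kernel
        self.decoder_variant = decoder_variant
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.lr_power = lr_power
        self.augment = augment
        self.threshold = threshold
        self.stop_train_dsc = stop_train_dsc
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _arch(self):
        return ArchConfig(num_classes=self.num_classes,
                          stage_channels=tuple(self.stage_channels),
                          dwd_kernel=self.dwd_kernel,
                          decoder_variant=self.decoder_variant)

    @staticmethod
    def _to_samples(X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 3 or y.shape != X.shape:
            raise ValueError("X must be (n, H, W) grayscale in [0, 1] and y "
                             "an equally shaped integer label stack")
        return [Sample(image=xi, mask=yi.astype(np.uint8), meta={})
                for xi, yi in zip(X, y)]

    def fit(self, X, y):
        samples = self._to_samples(X, y)
        if self.validation_fraction > 0 and len(samples) > 1:
            n_val = max(1, int(round(self.validation_fraction * len(samples))))
            val, trn = samples[:n_val], samples[n_val:]
        else:
            val, trn = samples, samples
        self.model_ = build_model(self._arch(), seed=self.seed)
        self.history_, best = fit_arrays(
            self.model_, trn, val, epochs=self.epochs,
            batch_size=self.batch_size, lr=self.lr,
            weight_decay=self.weight_decay, lr_power=self.lr_power,
            seed=self.seed, augment_train=self.augment,
            threshold=self.threshold, stop_train_dsc=self.stop_train_dsc)
        self.best_epoch_ = best["epoch"]
        self.model_.load_state_dict(best["state"])
        self.model_.eval()
        return self

    def predict_proba(self, X):
        """Per-class foreground probabilities, shape (n, C, H, W)."""
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=np.float32)
        images = [normalize(xi) for xi in X]
        return _forward_probs(self.model_, images, self.batch_size)

    def predict(self, X):
        """Integer label masks, shape (n, H, W)."""
        probs = self.predict_proba(X)
        return np.stack([mask_from_probs(p, self.threshold) for p in probs])

    def score(self, X, y):
        """Mean Dice similarity coefficient over samples and classes."""
        preds = self.predict(X)
        y = np.asarray(y)
        scores = [
            seg_metrics(p, t, n_classes=self.num_classes,
                        compute_hd95=False).mean["dsc"]
            for p, t in zip(preds, y)
        ]
        return float(np.mean(scores))
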