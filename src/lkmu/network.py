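"""Assembly of the five-stage U-shaped LKMU-Lite segmentation network.

Encoder stages pair a DLKA block (where the stage channel change happens)
with an MSGP block, with 2x2 max pooling between stages.  The decoder
mirrors the encoder with four Aggregating-Shift stages, each consuming the
bilinear x2 upsampling of the previous stage concatenated with the
same-stage skip feature.  A pointwise prediction head maps the final
32-channel feature map to one logit channel per foreground class
(background is implicit; each class gets an independent sigmoid).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .blocks import AggShiftDecoder, Conv3x3Decoder, DLKA, MSGP, receptive_field
from .nn import autograd as ag

__all__ = ["ArchConfig", "LKMULite", "build_model", "predict_mask",
           "mask_from_probs"]

DECODER_VARIANTS = ("aggshift", "conv3x3_mod", "conv3x3")


@dataclass(frozen=True)
class ArchConfig:
    """Structural description of the network.

    ``dwd_kernel`` selects the receptive-field ablation settings: 3, 5, 7
    and 9 give equivalent receptive fields of 13, 23, 33 and 43 at
    dilation 5.
    """

    in_channels: int = 3
    num_classes: int = 1
    stage_channels: tuple = (32, 64, 128, 160, 256)
    dw_kernel: int = 3
    dwd_kernel: int = 7
    dwd_dilation: int = 5
    msgp_rates: tuple = (3, 7, 11)
    msgp_adder: str = "raw"
    decoder_variant: str = "aggshift"

    def __post_init__(self):
        if len(self.stage_channels) != 5:
            raise ValueError("exactly 5 encoder stages are required")
        if any(c % 4 for c in self.stage_channels):
            raise ValueError("all stage channels must be divisible by 4")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if self.decoder_variant not in DECODER_VARIANTS:
            raise ValueError(
                f"decoder_variant must be one of {DECODER_VARIANTS}")
        # validates kernel parity / dilation positivity
        receptive_field(self.dw_kernel, self.dwd_kernel, self.dwd_dilation)
        object.__setattr__(self, "stage_channels", tuple(self.stage_channels))
        object.__setattr__(self, "msgp_rates", tuple(self.msgp_rates))

    @property
    def dlka_receptive_field(self):
        return receptive_field(self.dw_kernel, self.dwd_kernel,
                               self.dwd_dilation)

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["stage_channels"] = list(self.stage_channels)
        d["msgp_rates"] = list(self.msgp_rates)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if "stage_channels" in d:
            d["stage_channels"] = tuple(d["stage_channels"])
        if "msgp_rates" in d:
            d["msgp_rates"] = tuple(d["msgp_rates"])
        return cls(**d)

    def to_json(self):
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s):
        return cls.from_dict(json.loads(s))


class _EncoderStage(nn.Module):
    def __init__(self, cfg, in_channels, out_channels, rng):
        super().__init__()
        self.dlka = DLKA(in_channels, out_channels, dw_kernel=cfg.dw_kernel,
                         dwd_kernel=cfg.dwd_kernel, dilation=cfg.dwd_dilation,
                         rng=rng)
        self.msgp = MSGP(out_channels, rates=cfg.msgp_rates,
                         adder=cfg.msgp_adder, rng=rng)

    def forward(self, x):
        return self.msgp(self.dlka(x))


class LKMULite(nn.Module):
    def __init__(self, cfg: ArchConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        ch = cfg.stage_channels
        ins = (cfg.in_channels,) + ch[:-1]
        self.encoder = nn.ModuleList([
            _EncoderStage(cfg, ins[i], ch[i], rng) for i in range(5)
        ])
        self.pool = nn.MaxPool2d()
        self.up = nn.BilinearUpsample2x()
        decoders = []
        prev = ch[-1]
        for skip in reversed(ch[:-1]):  # 160, 128, 64, 32
            cat = prev + skip
            if cfg.decoder_variant == "conv3x3":
                decoders.append(Conv3x3Decoder(cat, skip, rng=rng))
            else:
                decoders.append(AggShiftDecoder(cat, skip,
                                                variant=cfg.decoder_variant,
                                                rng=rng))
            prev = skip
        self.decoder = nn.ModuleList(decoders)
        self.head = nn.Conv2d(ch[0], cfg.num_classes, 1, bias=True, rng=rng)

    def forward(self, x):
        if not isinstance(x, ag.Tensor):
            x = ag.Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 4:
            raise ValueError("expected a 4-D (batch, channel, H, W) input")
        _, c, h, w = x.shape
        if c != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {c}")
        if h % 16 or w % 16:
            raise ValueError(
                f"spatial dimensions must be divisible by 16 (five stages "
                f"with four 2x2 poolings); got {h}x{w} — pad or resize the "
                f"input")
        feats = self.forward_features(x)
        return self.head(feats[-1])

    def forward_features(self, x):
        """Runs the full encoder/decoder and returns every stage output
        (5 encoder feature maps followed by 4 decoder feature maps)."""
        if not isinstance(x, ag.Tensor):
            x = ag.Tensor(np.asarray(x, dtype=np.float32))
        skips = []
        h = x
        for i, stage in enumerate(self.encoder):
            h = stage(h)
            skips.append(h)
            if i < 4:
                h = self.pool(h)
        outs = list(skips)
        y = skips[-1]
        for dec, skip in zip(self.decoder, reversed(skips[:-1])):
            y = dec(ag.concat([self.up(y), skip], axis=1))
            outs.append(y)
        return outs


def build_model(cfg: ArchConfig = None, seed: int = 0, **overrides) -> LKMULite:
    """Builds a seeded LKMU-Lite; keyword overrides update the config."""
    if cfg is None:
        cfg = ArchConfig(**overrides)
    elif overrides:
        cfg = ArchConfig(**{**cfg.to_dict(), **overrides})
    return LKMULite(cfg, seed=seed)


def _sigmoid(z):
    from scipy.special import expit

    return expit(np.asarray(z, dtype=np.float64))


def mask_from_probs(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Per-class probabilities (C, H, W) -> integer label mask (H, W).

    A pixel is foreground for class c where p_c > threshold; where several
    classes exceed the threshold the most probable one wins; 0 means
    background.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    probs = np.asarray(probs)
    above = probs > threshold
    best = probs.argmax(axis=0)
    mask = np.where(above.any(axis=0), best + 1, 0)
    return mask.astype(np.uint8)


def predict_mask(model: LKMULite, image, threshold: float = 0.5) -> np.ndarray:
    """Predicts an integer label mask for one image.

    ``image`` is either a raw grayscale (H, W) array in [0, 1] — it is
    replicated to three channels and ImageNet-normalized — or an already
    normalized (C, H, W) array.
    """
    from .phantom import normalize  # local import to avoid a cycle

    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 2:
        image = normalize(image)
    model.eval()
    with ag.no_grad():
        logits = model(image[None]).data[0]
    probs = _sigmoid(logits)
    return mask_from_probs(probs, threshold)
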