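"""Analytic parameter and operation counting.

The counter walks a real (batch-1) forward pass with a recorder attached,
so it is exact for every architecture variant and never drifts from the
executed graph.  Counting convention (the one that reproduces the printed
complexity figures of lightweight-segmentation work):

* convolution: one multiply-accumulate per output element per kernel tap
  per input channel per group (``out_elems * (cin/groups) * k^2``); bias
  additions are not counted;
* batch normalization: 2 ops per element (scale and shift);
* ReLU: 1 op per element;
* 2x2 max pooling: one comparison per kernel tap per output element (4);
* bilinear upsampling: 1 op per output element;
* elementwise additions / Hadamard products and the parameter-free
  spatial shift: zero.

Totals are reported as "FLOPs" in G, matching the field's convention of
quoting MAC-dominated counts under that name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import LKMULite
from .nn import autograd as ag
from .nn.modules import _ProfileRecorder

__all__ = ["ComplexityReport", "count_parameters", "count_macs"]


@dataclass
class ComplexityReport:
    rows: list = field(default_factory=list)
    input_shape: tuple | None = None

    @property
    def total_params(self) -> int:
        return int(sum(r["params"] for r in self.rows))

    @property
    def total_macs(self) -> int:
        return int(sum(r["macs"] for r in self.rows))

    @property
    def params_M(self) -> float:
        return round(self.total_params / 1e6, 2)

    @property
    def flops_G(self) -> float:
        return round(self.total_macs / 1e9, 2)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=["name", "type", "params", "macs"])
        total = pd.DataFrame([{"name": "TOTAL", "type": "",
                               "params": self.total_params,
                               "macs": self.total_macs}])
        return pd.concat([df, total], ignore_index=True)

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    def conv_macs(self) -> int:
        """Subtotal over convolution layers only (the spec's stricter
        convention; does not reproduce the printed FLOPs figures)."""
        return int(sum(r["macs"] for r in self.rows if r["type"] == "Conv2d"))


def _profile(model, input_shape):
    was_training = model.training
    model.eval()
    for name, mod in model.named_modules():
        object.__setattr__(mod, "_prof_name", name)
    x = ag.Tensor(np.zeros((1,) + tuple(input_shape), dtype=np.float32))
    with ag.no_grad(), _ProfileRecorder() as rec:
        model(x)
    if was_training:
        model.train()
    return rec.rows


def count_parameters(model) -> ComplexityReport:
    """Per-layer trainable parameter counts.

    Rows are one per parameter-owning leaf layer; the total equals a
    brute-force enumeration of the model's parameter registry exactly.
    """
    rows = []
    for name, mod in model.named_modules():
        if mod._params:
            rows.append({
                "name": name or type(mod).__name__,
                "type": type(mod).__name__,
                "params": int(sum(p.data.size for p in mod._params.values())),
                "macs": 0,
            })
    report = ComplexityReport(rows=rows)
    registry_total = sum(p.data.size for _, p in model.named_parameters())
    assert report.total_params == registry_total
    return report


def count_macs(model, input_shape=(3, 256, 256)) -> ComplexityReport:
    """Per-layer parameter and operation counts for a batch-1 forward pass
    at ``input_shape`` = (channels, height, width)."""
    c, h, w = input_shape
    if isinstance(model, LKMULite) and (h % 16 or w % 16):
        raise ValueError("height and width must be divisible by 16")
    rows = _profile(model, input_shape)
    return ComplexityReport(rows=rows, input_shape=tuple(input_shape))
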