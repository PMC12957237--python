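"""Sandwich-enhanced CBAM classifier and its ablation/ordering variants.

The full model (variant ``SCBAM``) wraps the two CBAM attention blocks in
a convolutional sandwich. For a per-window feature map treated as a
1-channel 12 x 6 image (CSP components x rhythm bands):

    conv 128 @ 5x5 (same padding) + ReLU
    filter attention      (reduction ratio 16 -> hidden width 8)
    spatial-rhythm attention (3x3 conv on [avg; max] filter pooling)
    conv 32 @ 3x3 (same padding) + ReLU
    max pool 2x2 / stride 2
    flatten -> dense 64 + ReLU -> dropout 0.3 -> dense n_classes, softmax

Writing M for a feature map, the attention blocks compute
M' = A_f(M) (x) M and M'' = A_cr(M') (x) M' where A_f is the sigmoid of a
shared two-layer MLP applied to global-average- and max-pooled filter
descriptors, and A_cr is the sigmoid of a single 3x3 convolution over the
2-channel [average; max] pooling across filters. Both attention maps
therefore lie strictly in (0, 1).

Variants systematically remove or reorder these pieces: ``SA2A1`` swaps
the attention order, ``C-SCBAM``/``SCBAM-C`` add an extra convolution
before/after the sandwich, ``fCBAM`` drops the second convolution,
``CBAMs`` the first, ``SA1``/``SA2`` keep only one attention block inside
the sandwich, ``CBAM`` keeps only the attention blocks, and
``two_convs`` removes attention entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidArgumentError
from .nn import (
    Conv2D,
    Dense,
    Dropout,
    FilterAttention,
    Flatten,
    MaxPool2D,
    Network,
    ReLU,
    SpatialAttention,
)

__all__ = ["ScbamConfig", "ScbamNet", "build_model", "VARIANTS"]

VARIANTS = ("SCBAM", "SA2A1", "C-SCBAM", "SCBAM-C", "fCBAM", "CBAMs",
            "SA1", "SA2", "CBAM", "two_convs")

#: recognised but unimplemented design-phase identifiers (transformer and
#: self-attention variants); requesting one raises a clear error.
UNIMPLEMENTED_VARIANTS = ("CTF", "CSA")


@dataclass(frozen=True)
class ScbamConfig:
    """Architecture hyperparameters; defaults are the full-size model."""

    conv1_filters: int = 128
    conv1_kernel: tuple = (5, 5)
    reduction_ratio: int = 16
    spatial_kernel: tuple = (3, 3)
    conv2_filters: int = 32
    conv2_kernel: tuple = (3, 3)
    extra_conv_filters: int = 32
    pool: tuple = (2, 2)
    dropout: float = 0.3
    dense_hidden: int = 64
    n_classes: int = 2
    input_shape: tuple = (1, 12, 6)
    variant: str = "SCBAM"

    def validate(self):
        if self.variant in UNIMPLEMENTED_VARIANTS:
            raise InvalidArgumentError(
                f"variant {self.variant!r} is a recognised design identifier "
                "but is not implemented"
            )
        if self.variant not in VARIANTS:
            raise InvalidArgumentError(f"unknown variant {self.variant!r}")
        has_conv1 = self.variant not in ("CBAMs", "CBAM")
        if has_conv1 and self.conv1_filters % self.reduction_ratio != 0:
            raise InvalidArgumentError(
                "reduction_ratio must divide conv1_filters"
            )


class ScbamNet:
    """A built (and possibly trained) classifier network.

    Thin wrapper over the sequential :class:`~scbam.nn.Network` exposing
    the pieces evaluation code needs: probability prediction, a printable
    summary, and introspection of the attention blocks.
    """

    def __init__(self, config: ScbamConfig, network: Network):
        self.config = config
        self.network = network

    def forward(self, x, train=False):
        return self.network.forward(np.asarray(x, dtype=float), train=train)

    def predict_proba(self, x):
        """Class-probability rows (softmax; each row sums to 1)."""
        return self.network.predict_proba(np.asarray(x, dtype=float))

    def predict(self, x):
        return self.predict_proba(x).argmax(axis=1)

    def n_params(self) -> int:
        return self.network.n_params()

    def attention_layers(self):
        return [l for l in self.network.layers
                if isinstance(l, (FilterAttention, SpatialAttention))]

    @property
    def filter_attention_hidden_width(self):
        """Hidden width of the shared MLP in the filter-attention block
        (filters / reduction ratio), or None if the variant has none."""
        for layer in self.network.layers:
            if isinstance(layer, FilterAttention):
                return layer.hidden_width
        return None

    def summary(self):
        return self.network.summary()

    def summary_text(self) -> str:
        rows = self.summary()
        lines = [f"{'layer':<24}{'output shape':<18}{'params':>8}"]
        for r in rows:
            lines.append(f"{r['layer']:<24}{str(r['output_shape']):<18}"
                         f"{r['n_params']:>8}")
        lines.append(f"{'total':<42}{self.n_params():>8}")
        return "\n".join(lines)


def _attention_blocks(cfg: ScbamConfig, n_filters: int):
    """(filter attention, spatial attention) sized for n_filters maps.

    When the variant has no leading convolution the attention operates on
    the single input map; the reduction ratio is then forced to 1 so the
    MLP stays well-defined.
    """
    r = cfg.reduction_ratio if n_filters % cfg.reduction_ratio == 0 else 1
    return (FilterAttention(n_filters, r),
            SpatialAttention(cfg.spatial_kernel))


def build_model(config: ScbamConfig, seed: int = 0,
                dropout_seed: int | None = None) -> ScbamNet:
    """Assemble and initialize the requested architecture variant.

    Deterministic: weights come from ``seed``; the dropout stream from
    ``dropout_seed`` (defaults to ``seed + 1``).
    """
    cfg = config
    cfg.validate()
    in_ch, h, w = cfg.input_shape
    drop_rng = np.random.default_rng(
        seed + 1 if dropout_seed is None else dropout_seed)

    layers = []
    current = in_ch
    variant = cfg.variant

    if variant == "C-SCBAM":
        layers += [Conv2D(current, cfg.extra_conv_filters, cfg.conv2_kernel,
                          name="conv_extra"), ReLU()]
        current = cfg.extra_conv_filters

    if variant not in ("CBAMs", "CBAM"):
        layers += [Conv2D(current, cfg.conv1_filters, cfg.conv1_kernel,
                          name="conv1"), ReLU()]
        current = cfg.conv1_filters

    fa, sa = _attention_blocks(cfg, current)
    if variant in ("SCBAM", "C-SCBAM", "SCBAM-C", "fCBAM", "CBAMs", "CBAM"):
        layers += [fa, sa]
    elif variant == "SA2A1":
        layers += [sa, fa]
    elif variant == "SA1":
        layers += [fa]
    elif variant == "SA2":
        layers += [sa]
    # two_convs: no attention at all

    if variant not in ("fCBAM", "CBAM"):
        layers += [Conv2D(current, cfg.conv2_filters, cfg.conv2_kernel,
                          name="conv2"), ReLU()]
        current = cfg.conv2_filters

    if variant == "SCBAM-C":
        layers += [Conv2D(current, cfg.extra_conv_filters, cfg.conv2_kernel,
                          name="conv_extra"), ReLU()]
        current = cfg.extra_conv_filters

    layers += [MaxPool2D(cfg.pool), Flatten()]
    flat = current * (h // cfg.pool[0]) * (w // cfg.pool[1])
    layers += [
        Dense(flat, cfg.dense_hidden, name="dense_hidden"), ReLU(),
        Dropout(cfg.dropout, rng=drop_rng),
        Dense(cfg.dense_hidden, cfg.n_classes, name="dense_out"),
    ]

    net = Network(layers, cfg.input_shape)
    net.init_params(seed)
    return ScbamNet(cfg, net)
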