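"""Classifier architectures: the asymmetry-aware ensemble CNN and references.

Every variant is an ensemble of six identical (but independently
parameterized) feature-extraction branches — one per hemodynamic indicator
— whose flattened outputs are concatenated and fed to a shared
classification block of three dense layers (softmax output over HC/MDD).

Variants
--------
``proposed``
    Depthwise temporal convolution (kernel 32, stride 16: 4-s windows with
    2-s overlap at 8.138 Hz) per channel, then two depthwise channel-axis
    convolutions of kernel 2 / stride 2.  On the canonical interleaved
    channel stacking the first spatial layer embeds each left/right mirror
    pair and the second merges adjacent pair-units, so the learned spatial
    features encode inter-hemispheric asymmetry.  Branch output 14x17,
    ensemble flatten 1,428.
``c1``
    Temporal layer only (no spatial structure); flatten 5,712.
``c2``
    Spatial-first: the two channel-axis convolutions run before the
    temporal one; flatten 1,428.
``c3``
    The proposed topology applied after a seeded random permutation of the
    channel axis, destroying the mirror-pair structure the spatial layers
    rely on.
``eegnet`` / ``shallowconvnet``
    The feature-extraction blocks of the two standard EEG decoding CNNs,
    with their spatial layers sized so each branch also flattens to 238
    (ensemble 1,428) and their original classifier stages removed.

All convolutions use valid padding.  Batch norm follows each convolution
where the reference architectures prescribe it; hidden dense widths default
to (64, 16), a deliberately small funnel for ~10^2 training subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .montage import randomized_order

VARIANTS = ("proposed", "c1", "c2", "c3", "eegnet", "shallowconvnet")

__all__ = [
    "VARIANTS",
    "ModelConfig",
    "build_feature_extractor",
    "build_classifier",
    "build_model",
    "flatten_dim",
    "architecture_summary",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters shared by the variant builders."""

    variant: str = "proposed"
    n_indicators: int = 6
    n_times: int = 246
    n_channels: int = 68
    temporal_kernel: int = 32
    temporal_stride: int = 16
    spatial_kernel: int = 2
    spatial_stride: int = 2
    dropout: float = 0.4
    dense_units: tuple[int, int] = (64, 16)
    c3_order_seed: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.n_channels % (self.spatial_stride**2) != 0:
            raise ValueError("n_channels must tile under two stride-2 spatial layers")


def _conv_bn_elu(kernel: int, stride: int) -> list[nn.Layer]:
    return [
        nn.DepthwiseConv1D(kernel, stride),
        nn.BatchNorm(),
        nn.Activation("elu"),
    ]


def _proposed_branch(cfg: ModelConfig, reorder: np.ndarray | None = None) -> nn.Sequential:
    layers: list[nn.Layer] = []
    if reorder is not None:
        layers.append(nn.ChannelReorder(reorder))
    layers += _conv_bn_elu(cfg.temporal_kernel, cfg.temporal_stride)  # (14, 68)
    layers.append(nn.Permute())  # (68, 14)
    layers += _conv_bn_elu(cfg.spatial_kernel, cfg.spatial_stride)  # (34, 14): pairs
    layers += _conv_bn_elu(cfg.spatial_kernel, cfg.spatial_stride)  # (17, 14): adjacent
    layers.append(nn.Permute())  # (14, 17)
    layers.append(nn.Flatten())
    layers.append(nn.Dropout(cfg.dropout))
    return nn.Sequential(layers)


def _c1_branch(cfg: ModelConfig) -> nn.Sequential:
    layers = _conv_bn_elu(cfg.temporal_kernel, cfg.temporal_stride)  # (14, 68)
    layers += [nn.Flatten(), nn.Dropout(cfg.dropout)]
    return nn.Sequential(layers)


def _c2_branch(cfg: ModelConfig) -> nn.Sequential:
    layers: list[nn.Layer] = [nn.Permute()]  # (68, 246)
    layers += _conv_bn_elu(cfg.spatial_kernel, cfg.spatial_stride)  # (34, 246)
    layers += _conv_bn_elu(cfg.spatial_kernel, cfg.spatial_stride)  # (17, 246)
    layers.append(nn.Permute())  # (246, 17)
    layers += _conv_bn_elu(cfg.temporal_kernel, cfg.temporal_stride)  # (14, 17)
    layers += [nn.Flatten(), nn.Dropout(cfg.dropout)]
    return nn.Sequential(layers)


def _eegnet_branch(cfg: ModelConfig) -> nn.Sequential:
    # input (246, 68) -> rows x time (68, 246)
    return nn.Sequential(
        [
            nn.Permute(),
            nn.TemporalConv2D(16, 4),  # (68, 58)
            nn.BatchNorm(per_feature=False),
            nn.SpatialCollapse(17, max_norm=1.0),  # (58, 17)
            nn.BatchNorm(),
            nn.Activation("elu"),
            nn.AvgPoolTime(8, 2),  # (26, 17)
            nn.Dropout(cfg.dropout),
            nn.DepthwiseConv1D(8, 1),  # separable conv, depthwise part: (19, 17)
            nn.PointwiseMix(17),  # separable conv, pointwise part
            nn.BatchNorm(),
            nn.Activation("elu"),
            nn.AvgPoolTime(6, 1),  # (14, 17)
            nn.Flatten(),
        ]
    )


def _shallow_branch(cfg: ModelConfig) -> nn.Sequential:
    return nn.Sequential(
        [
            nn.Permute(),
            nn.TemporalConv2D(16, 4, max_norm=2.0),  # (68, 58)
            nn.SpatialCollapse(17, max_norm=2.0),  # (58, 17)
            nn.BatchNorm(eps=1e-5, momentum=0.1),
            nn.Activation("square"),
            nn.AvgPoolTime(5, 4),  # (14, 17)
            nn.Activation("log"),
            nn.Dropout(cfg.dropout),
            nn.Flatten(),
        ]
    )


def build_feature_extractor(cfg: ModelConfig) -> list[nn.Sequential]:
    """One freshly parameterized branch per indicator for ``cfg.variant``."""
    builders = {
        "proposed": lambda: _proposed_branch(cfg),
        "c1": lambda: _c1_branch(cfg),
        "c2": lambda: _c2_branch(cfg),
        "c3": lambda: _proposed_branch(
            cfg, reorder=randomized_order(cfg.c3_order_seed, cfg.n_channels)
        ),
        "eegnet": lambda: _eegnet_branch(cfg),
        "shallowconvnet": lambda: _shallow_branch(cfg),
    }
    return [builders[cfg.variant]() for _ in range(cfg.n_indicators)]


def build_classifier(cfg: ModelConfig) -> nn.Sequential:
    """Shared classification block: three dense layers, softmax via the loss."""
    d1, d2 = cfg.dense_units
    return nn.Sequential(
        [
            nn.Dense(d1),
            nn.Activation("elu"),
            nn.Dense(d2),
            nn.Activation("elu"),
            nn.Dense(2),
        ]
    )


def build_model(cfg: ModelConfig, seed: int | None = None) -> nn.EnsembleNet:
    """Assemble and initialize the full ensemble network for ``cfg.variant``."""
    return nn.EnsembleNet(
        branches=build_feature_extractor(cfg),
        head=build_classifier(cfg),
        branch_input_shape=(cfg.n_times, cfg.n_channels),
        seed=cfg.seed if seed is None else seed,
    )


def flatten_dim(cfg: ModelConfig) -> int:
    """Concatenated flattened feature dimension fed to the classifier."""
    return build_model(cfg).n_features


def architecture_summary(cfg: ModelConfig) -> dict:
    """Layer-by-layer description of one branch plus the ensemble shapes.

    ``branch`` lists each layer with its per-sample output shape (no batch
    axis); ``concatenate_shape`` appends the ensemble axis; ``flatten`` is
    the classifier input width.  Used by the shape-audit tests and the
    architecture-report CLI.
    """
    model = build_model(cfg)
    branch = model.branches[0]
    rows = []
    for layer in branch.layers:
        d = layer.describe()
        d["output_shape"] = tuple(int(v) for v in layer.out_shape) if layer.out_shape else None
        rows.append(d)
    per_branch = branch.layers[-1].out_shape
    # shape of the stacked branch outputs before flattening, ensemble-last
    pre_flatten = next(
        (l.out_shape for l in reversed(branch.layers) if not isinstance(l, (nn.Flatten, nn.Dropout))),
        None,
    )
    return {
        "variant": cfg.variant,
        "branch": rows,
        "n_branches": cfg.n_indicators,
        "concatenate_shape": tuple(pre_flatten) + (cfg.n_indicators,),
        "flatten": int(model.n_features),
        "per_branch_flatten": int(per_branch[0]) if per_branch else None,
    }
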