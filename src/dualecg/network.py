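"""The dual-channel separable-convolution architecture.

Channel 1 consumes the 1201-sample 3-beat segment (spatial features,
kernel 5); channel 2 consumes the 292-sample stacked D3-D5 wavelet vector
(spectral features, kernel 3).  Each channel opens with one standard Conv1D
that lifts the single-channel signal to ``initial_filters`` feature maps,
followed by two *functional units*; the merged branches pass through one
more functional unit, a max-pool, and four dense layers ending in a 4-way
softmax.

A functional unit is two depthwise-separable convolutions — the second with
stride 2 — each followed by batch normalization and an ELU activation; it
doubles the channel depth and halves the temporal length.

Closed-form parameter and operation counters for standard and separable
convolutions are provided alongside the builder, so the model's actual
weight-array sizes can be audited against the formulas:

* standard:  ``Np = k * Ci * Co``,  ``No = l_in * Np``
* separable: ``Np = k * Ci + Ci * Co``,  ``No = l_in * Np``
* ratio:     ``Np_sep / Np_std = (Co + k) / (k * Co)``
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    ELU,
    BatchNorm,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    MaxPool1D,
    SepConv1D,
    Softmax,
)
from .nn.model import DualBranchModel

CONV_KINDS = ("conv1d", "sepconv1d")


# ---------------------------------------------------------------------------
# Closed-form counters


def np_conv1d(k: int, Ci: int, Co: int) -> int:
    """Weight count of a standard 1-D convolution (no bias): k*Ci*Co."""
    if min(k, Ci, Co) < 1:
        raise ValueError("k, Ci, Co must all be >= 1")
    return k * Ci * Co


def np_sepconv1d(k: int, Ci: int, Co: int) -> int:
    """Weight count of a depthwise separable 1-D convolution: k*Ci + Ci*Co."""
    if min(k, Ci, Co) < 1:
        raise ValueError("k, Ci, Co must all be >= 1")
    return k * Ci + Ci * Co


def param_ratio(k: int, Co: int) -> float:
    """Separable/standard parameter ratio: (Co + k) / (k * Co)."""
    return (Co + k) / (k * Co)


def elu(x: float, alpha: float = 1.0) -> float:
    """Scalar exponential linear unit: x if x > 0 else alpha*(e^x - 1)."""
    return float(x) if x > 0 else alpha * (np.exp(x) - 1.0)


# ---------------------------------------------------------------------------
# Architecture description


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the architecture, as counted by the layer census."""

    kind: str
    k: int = 0
    c_in: int = 0
    c_out: int = 0
    stride: int = 1
    l_in: int = 0
    l_out: int = 0

    def param_count(self) -> int:
        if self.kind == "conv1d":
            return np_conv1d(self.k, self.c_in, self.c_out)
        if self.kind == "sepconv1d":
            return np_sepconv1d(self.k, self.c_in, self.c_out)
        raise ValueError(f"no closed-form count for kind {self.kind!r}")


def op_count(layer: LayerSpec) -> int:
    """Operation count of a conv-type layer: l_in * Np."""
    if layer.kind not in CONV_KINDS:
        raise ValueError(f"op_count applies to conv layers, not {layer.kind!r}")
    if layer.l_in < 1:
        raise ValueError("layer.l_in must be set")
    return layer.l_in * layer.param_count()


@dataclass
class ModelConfig:
    """Every architecture hyperparameter.

    ``dense_sizes`` defaults to (256, 64, 16); the published search chose
    dense sizes/dropouts by sequential model-based optimization without
    printing the winners, so these are defaults, not claims.
    """

    k_ch1: int = 5
    k_ch2: int = 3
    initial_filters: int = 16
    n_units_ch1: int = 2
    n_units_ch2: int = 2
    n_units_post: int = 1
    dense_sizes: tuple[int, ...] = (256, 64, 16)
    softmax_classes: int = 4
    dropout_ps: tuple[float, float] = (0.5, 0.2)
    activation_alpha: float = 1.0
    initial_activation: bool = False
    maxpool_pool: int = 2
    input_len1: int = 1201
    input_len2: int = 292

    #: expected layer census (total conv, batchnorm, activation, maxpool, dense)
    EXPECTED_CENSUS = {"conv_total": 12, "batchnorm": 10, "activation": 10,
                       "maxpool": 1, "dense": 4}


def build_functional_unit(c_in: int, k: int, l_in: int) -> list[LayerSpec]:
    """Spec of one functional unit: [sepconv s1, BN, elu, sepconv s2, BN, elu].

    Output depth ``2*c_in``; output length ``ceil(l_in/2)``.
    """
    if c_in < 1:
        raise ValueError("c_in must be >= 1")
    c_out = 2 * c_in
    l_half = -(-l_in // 2)
    return [
        LayerSpec("sepconv1d", k, c_in, c_out, 1, l_in, l_in),
        LayerSpec("batchnorm", c_in=c_out, c_out=c_out, l_in=l_in, l_out=l_in),
        LayerSpec("activation", c_in=c_out, c_out=c_out, l_in=l_in, l_out=l_in),
        LayerSpec("sepconv1d", k, c_out, c_out, 2, l_in, l_half),
        LayerSpec("batchnorm", c_in=c_out, c_out=c_out, l_in=l_half, l_out=l_half),
        LayerSpec("activation", c_in=c_out, c_out=c_out, l_in=l_half, l_out=l_half),
    ]


def _branch_specs(cfg: ModelConfig, k: int, n_units: int, l_in: int) -> list[LayerSpec]:
    # initial conv: an ELU can be fused into it (cfg.initial_activation);
    # a fused activation is part of the conv layer, not a census entry
    specs = [LayerSpec("conv1d", k, 1, cfg.initial_filters, 1, l_in, l_in)]
    c, L = cfg.initial_filters, l_in
    for _ in range(n_units):
        specs.extend(build_functional_unit(c, k, L))
        c, L = 2 * c, -(-L // 2)
    return specs


def layer_specs(cfg: ModelConfig) -> dict[str, list[LayerSpec]]:
    """Full architecture description: branch1, branch2 and trunk layer lists."""
    b1 = _branch_specs(cfg, cfg.k_ch1, cfg.n_units_ch1, cfg.input_len1)
    b2 = _branch_specs(cfg, cfg.k_ch2, cfg.n_units_ch2, cfg.input_len2)
    c1, L1 = b1[-1].c_out, b1[-1].l_out
    c2, L2 = b2[-1].c_out, b2[-1].l_out
    if c1 != c2:
        raise ValueError(
            f"branches exit with different channel counts ({c1} vs {c2}); "
            "cannot concatenate along the time axis"
        )
    # merge along the time axis: equal channel depths, lengths add
    c, L = c1, L1 + L2
    trunk: list[LayerSpec] = [
        LayerSpec("concat", c_in=c, c_out=c, l_in=L, l_out=L)
    ]
    for _ in range(cfg.n_units_post):
        trunk.extend(build_functional_unit(c, cfg.k_ch2, L))
        c, L = 2 * c, -(-L // 2)
    L_pre, L = L, L // cfg.maxpool_pool
    trunk.append(LayerSpec("maxpool", c_in=c, c_out=c, l_in=L_pre, l_out=L))
    n_flat = c * L
    sizes = (n_flat,) + tuple(cfg.dense_sizes) + (cfg.softmax_classes,)
    for i, (a, b) in enumerate(zip(sizes, sizes[1:])):
        trunk.append(LayerSpec("dense", c_in=a, c_out=b, l_in=1, l_out=1))
        if i < len(cfg.dropout_ps):
            trunk.append(LayerSpec("dropout", c_in=b, c_out=b, l_in=1, l_out=1))
    trunk.append(LayerSpec("softmax", c_in=cfg.softmax_classes,
                           c_out=cfg.softmax_classes, l_in=1, l_out=1))
    return {"branch1": b1, "branch2": b2, "trunk": trunk}


def census_of(specs: dict[str, list[LayerSpec]]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for part in specs.values():
        for s in part:
            counts[s.kind] = counts.get(s.kind, 0) + 1
    counts["conv_total"] = counts.get("conv1d", 0) + counts.get("sepconv1d", 0)
    return counts


def validate_census(cfg: ModelConfig) -> dict[str, int]:
    """Check the config's census against the canonical layer counts."""
    counts = census_of(layer_specs(cfg))
    for key, expected in ModelConfig.EXPECTED_CENSUS.items():
        if counts.get(key, 0) != expected:
            raise ValueError(
                f"layer census violation: {key} = {counts.get(key, 0)}, "
                f"expected {expected}"
            )
    return counts


def write_model_summary(cfg: ModelConfig, path) -> None:
    """Layer table as CSV: kind, kernel, channels, lengths, weight count."""
    specs = layer_specs(cfg)
    lines = ["part,kind,k,c_in,c_out,stride,l_in,l_out,n_params"]
    for part, part_specs in specs.items():
        for s in part_specs:
            n = s.param_count() if s.kind in CONV_KINDS else ""
            lines.append(f"{part},{s.kind},{s.k},{s.c_in},{s.c_out},"
                         f"{s.stride},{s.l_in},{s.l_out},{n}")
    counts = census_of(specs)
    lines.append("")
    lines.append("census," + ",".join(f"{k}:{v}" for k, v in sorted(counts.items())))
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


def build_owcnn(cfg: ModelConfig | None = None, seed: int = 0,
                check_census: bool = True, dtype=np.float32) -> DualBranchModel:
    """Build the runtime model (numpy layers) from a config.

    Conv/sepconv layers carry no biases so their weight counts equal the
    closed-form Np formulas exactly; dense layers keep biases.  Weights are
    stored in ``dtype`` (single precision by default).
    """
    cfg = cfg or ModelConfig()
    if check_census:
        validate_census(cfg)
    specs = layer_specs(cfg)
    rng = np.random.default_rng(seed)
    dropout_iter = iter(cfg.dropout_ps)

    def realize(spec: LayerSpec):
        if spec.kind == "conv1d":
            act = ELU(cfg.activation_alpha) if cfg.initial_activation else None
            return Conv1D(spec.k, spec.c_in, spec.c_out, spec.stride,
                          bias=False, rng=rng, activation=act)
        if spec.kind == "sepconv1d":
            return SepConv1D(spec.k, spec.c_in, spec.c_out, spec.stride, rng=rng)
        if spec.kind == "batchnorm":
            return BatchNorm(spec.c_out)
        if spec.kind == "activation":
            return ELU(cfg.activation_alpha)
        if spec.kind == "maxpool":
            return MaxPool1D(cfg.maxpool_pool)
        if spec.kind == "dense":
            # hidden dense layers carry a fused ELU; the final (pre-softmax)
            # dense is linear
            hidden = spec.c_out != cfg.softmax_classes
            act = ELU(cfg.activation_alpha) if hidden else None
            return Dense(spec.c_in, spec.c_out, bias=True, rng=rng, activation=act)
        if spec.kind == "dropout":
            return Dropout(next(dropout_iter), rng=np.random.default_rng(rng.integers(2**31)))
        if spec.kind == "softmax":
            return Softmax()
        return None  # concat is handled by the model container

    branch1 = [realize(s) for s in specs["branch1"]]
    branch2 = [realize(s) for s in specs["branch2"]]
    trunk_specs = [s for s in specs["trunk"] if s.kind != "concat"]
    flat_idx = next(i for i, s in enumerate(trunk_specs) if s.kind == "dense")
    trunk = [realize(s) for s in trunk_specs[:flat_idx]] + [Flatten()] + [
        realize(s) for s in trunk_specs[flat_idx:]
    ]
    return DualBranchModel(branch1, branch2, trunk, concat_axis=1, dtype=dtype)
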