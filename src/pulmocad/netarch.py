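"""Config-driven builder and shape tracer for the multiscale dense/dilated
U-Net and the plain U-Net baseline.

The architecture is declared as an :class:`ArchTable` — an ordered list of
:class:`LayerSpec` rows naming each layer's kind, kernel, dilation, output
channels, in-plane scale and upstream sources — and the network is built
from the table.  The normative default table pins the channel counts of the
multiscale design: Conv1 32; encoder dense blocks D1-D3 of growth rate 3
projected to 128; a dilated branch of 96 per level; combined encoder
features Conv2/Conv3 of 224 and Conv4 of 480 at the 8x8 bottleneck (on a
512x512 input); decoder anchors Up6 = 512 + 480 = 992 post-concatenation,
Up8 = 1600, Up12 = 256; and an output head of two 1x1 convolutions ending
in a sigmoid, returning the input's channel count.

Spatial scales follow successive halving 512 -> 256 -> ... -> 8; each
encoder level halves twice (once entering its dense block, once in the
transition layer), the dilated branch pools in step.  Up-convolutions are
realized as a convolution at the incoming scale followed by
nearest-neighbour upsampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from pulmocad import _autograd as ag
from pulmocad._autograd import Tensor

__all__ = [
    "LayerSpec",
    "ArchTable",
    "ShapeTrace",
    "TableError",
    "default_multiscale_table",
    "reduced_multiscale_table",
    "baseline_unet_table",
    "build_network",
    "build_baseline_unet",
    "shape_trace",
    "dense_block",
    "count_params",
    "Network",
]


class TableError(ValueError):
    """An architecture table is internally inconsistent."""


@dataclass
class LayerSpec:
    """One row of an architecture table.

    scale is the in-plane downsampling factor relative to the input; block
    assigns the layer to a named fine-tuning group (Conv1..Conv5, Up6..Up12).
    options carries kind-specific settings (growth_rate, n_layers,
    bottleneck channels for dense blocks; upsample factor for upconvs;
    activation for conv/output layers).
    """

    name: str
    kind: str  # input | conv | dense_block | transition | dilated_conv
    #          # | pool | upconv | concat | output
    sources: list = field(default_factory=list)
    kernel: tuple = (3, 3)
    dilation: int = 1
    out_channels: int = 0
    scale: int = 1
    block: str = ""
    options: dict = field(default_factory=dict)


@dataclass
class ArchTable:
    """Ordered layer table from which a network is built and shape-traced."""

    layers: list
    input_channels: int = 1
    spatial_rank: int = 3
    pool_z: bool = True  # whether 3d mode also pools the z axis
    name: str = "custom"

    def __post_init__(self):
        self.validate()

    def layer(self, name: str) -> LayerSpec:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    def validate(self) -> None:
        seen: dict = {}
        for spec in self.layers:
            if spec.name in seen:
                raise TableError(f"duplicate layer name {spec.name}")
            for src in spec.sources:
                if src not in seen:
                    raise TableError(f"layer {spec.name}: unknown source {src}")
            if spec.kind == "concat":
                if len(spec.sources) != 2:
                    raise TableError(f"concat {spec.name} must name exactly two sources")
                total = sum(seen[s].out_channels for s in spec.sources)
                if spec.out_channels != total:
                    raise TableError(
                        f"concat {spec.name}: out_channels {spec.out_channels} "
                        f"!= sum of sources {total}"
                    )
                s0, s1 = (seen[s] for s in spec.sources)
                if s0.scale != s1.scale:
                    raise TableError(f"concat {spec.name}: source scales differ")
            if spec.kind == "dense_block" and spec.options.get("growth_rate", 3) != 3:
                raise TableError(f"dense block {spec.name}: growth rate must be 3")
            seen[spec.name] = spec

    def max_scale(self) -> int:
        return max(l.scale for l in self.layers)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "input_channels": self.input_channels,
            "spatial_rank": self.spatial_rank,
            "pool_z": self.pool_z,
            "layers": [asdict(l) for l in self.layers],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchTable":
        layers = [
            LayerSpec(
                name=l["name"],
                kind=l["kind"],
                sources=list(l.get("sources", [])),
                kernel=tuple(l.get("kernel", (3, 3))),
                dilation=int(l.get("dilation", 1)),
                out_channels=int(l.get("out_channels", 0)),
                scale=int(l.get("scale", 1)),
                block=l.get("block", ""),
                options=dict(l.get("options", {})),
            )
            for l in d["layers"]
        ]
        return cls(
            layers=layers,
            input_channels=int(d.get("input_channels", 1)),
            spatial_rank=int(d.get("spatial_rank", 3)),
            pool_z=bool(d.get("pool_z", True)),
            name=d.get("name", "custom"),
        )


@dataclass
class ShapeTrace:
    """Ordered (layer name, spatial dims, channels) records."""

    records: list  # of (name, tuple spatial, int channels)

    def channels(self, name: str) -> int:
        for n, _, c in self.records:
            if n == name:
                return c
        raise KeyError(name)

    def spatial(self, name: str) -> tuple:
        for n, s, _ in self.records:
            if n == name:
                return s
        raise KeyError(name)

    def __str__(self) -> str:
        lines = [f"{'layer':<10} {'spatial':<18} channels"]
        for n, s, c in self.records:
            lines.append(f"{n:<10} {'x'.join(str(v) for v in s):<18} {c}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# normative tables
# ---------------------------------------------------------------------------

def _encoder_level(layers, idx, src, src_ch, src_scale, dense_ch, dil_ch, out_name, block):
    """One multiscale encoder level: dense branch || dilated branch -> concat."""
    s2, s4 = src_scale * 2, src_scale * 4
    layers += [
        LayerSpec(f"P{idx}", "pool", [src], out_channels=src_ch, scale=s2, block=block),
        LayerSpec(
            f"D{idx}", "dense_block", [f"P{idx}"], out_channels=dense_ch, scale=s2,
            block=block, options={"growth_rate": 3, "n_layers": 4},
        ),
        LayerSpec(f"T{idx}", "transition", [f"D{idx}"], out_channels=dense_ch, scale=s4, block=block),
        LayerSpec(f"C{idx}d", "conv", [f"T{idx}"], (3, 3), 1, dense_ch, s4, block),
        LayerSpec(f"P{idx}b", "pool", [src], out_channels=src_ch, scale=s2, block=block),
        LayerSpec(f"P{idx}c", "pool", [f"P{idx}b"], out_channels=src_ch, scale=s4, block=block),
        LayerSpec(f"X{idx}", "dilated_conv", [f"P{idx}c"], (3, 3), 2, dil_ch, s4, block),
        LayerSpec(
            out_name, "concat", [f"C{idx}d", f"X{idx}"],
            out_channels=dense_ch + dil_ch, scale=s4, block=block,
        ),
    ]


def default_multiscale_table(input_channels: int = 1) -> ArchTable:
    """The normative multiscale dense/dilated U-Net table.

    Three encoder levels (dense blocks D1-D3 with dilated side branches),
    an 8x8 bottleneck on a 512x512 input, a seven-upconv decoder with two
    decoder-side dense blocks (D4, D5) and skip concatenations at Up6, Up8,
    Up10 and Up12, and a two-convolution sigmoid output head.
    """
    L: list = [
        LayerSpec("Input", "input", [], out_channels=input_channels, scale=1, block="Conv1"),
        LayerSpec("Conv1", "conv", ["Input"], (3, 3), 1, 32, 1, "Conv1"),
    ]
    _encoder_level(L, 1, "Conv1", 32, 1, 128, 96, "Conv2", "Conv2")
    _encoder_level(L, 2, "Conv2", 224, 4, 128, 96, "Conv3", "Conv3")
    _encoder_level(L, 3, "Conv3", 224, 16, 384, 96, "Conv4", "Conv4")
    L += [
        LayerSpec("Conv5", "conv", ["Conv4"], (3, 3), 1, 512, 64, "Conv5"),
        # decoder: conv-at-scale followed by nearest upsampling; Up6 stays
        # at the bottleneck scale (the nominal 512x8x8 deconvolution)
        LayerSpec("Up6pre", "upconv", ["Conv5"], (3, 3), 1, 512, 64, "Up6",
                  options={"upsample": 1}),
        LayerSpec("Up6", "concat", ["Up6pre", "Conv4"], out_channels=992, scale=64, block="Up6"),
        LayerSpec("Conv6", "conv", ["Up6"], (3, 3), 1, 480, 64, "Up6"),
        LayerSpec("Up7", "upconv", ["Conv6"], (3, 3), 1, 480, 32, "Up7"),
        LayerSpec("Up8pre", "upconv", ["Up7"], (3, 3), 1, 1376, 16, "Up8"),
        LayerSpec("Up8", "concat", ["Up8pre", "Conv3"], out_channels=1600, scale=16, block="Up8"),
        LayerSpec("Conv8", "conv", ["Up8"], (3, 3), 1, 224, 16, "Up8"),
        LayerSpec("Up9", "upconv", ["Conv8"], (3, 3), 1, 256, 8, "Up9"),
        LayerSpec("D4", "dense_block", ["Up9"], out_channels=256, scale=8, block="Up9",
                  options={"growth_rate": 3, "n_layers": 4}),
        LayerSpec("Up10pre", "upconv", ["D4"], (3, 3), 1, 256, 4, "Up10"),
        LayerSpec("Up10", "concat", ["Up10pre", "Conv2"], out_channels=480, scale=4, block="Up10"),
        LayerSpec("Up11", "upconv", ["Up10"], (3, 3), 1, 256, 2, "Up11"),
        LayerSpec("D5", "dense_block", ["Up11"], out_channels=256, scale=2, block="Up11",
                  options={"growth_rate": 3, "n_layers": 4}),
        LayerSpec("Up12pre", "upconv", ["D5"], (3, 3), 1, 224, 1, "Up12"),
        LayerSpec("Up12", "concat", ["Up12pre", "Conv1"], out_channels=256, scale=1, block="Up12"),
        LayerSpec("Out1", "conv", ["Up12"], (1, 1), 1, 32, 1, "Up12"),
        LayerSpec("Out", "output", ["Out1"], (1, 1), 1, input_channels, 1, "Up12",
                  options={"activation": "sigmoid"}),
    ]
    return ArchTable(layers=L, input_channels=input_channels, spatial_rank=3,
                     pool_z=True, name="default")


def reduced_multiscale_table(width_divisor: int = 8, input_channels: int = 1) -> ArchTable:
    """Desk-scale variant: one encoder level, channels divided by
    ``width_divisor``, in-plane pooling only (pool_z False) so 40x40x26
    patches pass through unchanged in z.  Block structure (dense block of
    growth 3, dilated branch, skip concats, upconv decoder with a dense
    block, two-conv sigmoid head) mirrors the default table.
    """

    def w(c: int) -> int:
        return max(c // width_divisor, 1)

    L: list = [
        LayerSpec("Input", "input", [], out_channels=input_channels, scale=1, block="Conv1"),
        LayerSpec("Conv1", "conv", ["Input"], (3, 3), 1, w(32), 1, "Conv1"),
    ]
    _encoder_level(L, 1, "Conv1", w(32), 1, w(128), w(96), "Conv2", "Conv2")
    c2 = w(128) + w(96)
    L += [
        LayerSpec("P2", "pool", ["Conv2"], out_channels=c2, scale=8, block="Conv5"),
        LayerSpec("Conv5", "conv", ["P2"], (3, 3), 1, w(512), 8, "Conv5"),
        LayerSpec("Up6pre", "upconv", ["Conv5"], (3, 3), 1, w(512), 4, "Up6",
                  options={"upsample": 2}),
        LayerSpec("Up6", "concat", ["Up6pre", "Conv2"], out_channels=w(512) + c2,
                  scale=4, block="Up6"),
        LayerSpec("Conv6", "conv", ["Up6"], (3, 3), 1, w(480), 4, "Up6"),
        LayerSpec("Up9", "upconv", ["Conv6"], (3, 3), 1, w(256), 2, "Up9"),
        LayerSpec("D4", "dense_block", ["Up9"], out_channels=w(256), scale=2, block="Up9",
                  options={"growth_rate": 3, "n_layers": 4}),
        LayerSpec("Up12pre", "upconv", ["D4"], (3, 3), 1, w(224), 1, "Up12"),
        LayerSpec("Up12", "concat", ["Up12pre", "Conv1"], out_channels=w(224) + w(32),
                  scale=1, block="Up12"),
        LayerSpec("Out1", "conv", ["Up12"], (1, 1), 1, w(32), 1, "Up12"),
        LayerSpec("Out", "output", ["Out1"], (1, 1), 1, input_channels, 1, "Up12",
                  options={"activation": "sigmoid"}),
    ]
    return ArchTable(layers=L, input_channels=input_channels, spatial_rank=3,
                     pool_z=False, name=f"reduced/{width_divisor}")


def baseline_unet_table(levels: int = 3, base_channels: int = 32,
                        input_channels: int = 1) -> ArchTable:
    """Symmetric plain U-Net: conv+pool encoder, upconv+skip+conv decoder,
    no dense blocks, no dilation."""
    if levels < 1:
        raise ValueError("levels must be >= 1")
    L = [LayerSpec("Input", "input", [], out_channels=input_channels, scale=1, block="Conv1")]
    src = "Input"
    enc = []
    for i in range(levels):
        ch = base_channels * (2**i)
        name = f"Enc{i + 1}"
        L.append(LayerSpec(name, "conv", [src], (3, 3), 1, ch, 2**i, f"Conv{i + 1}"))
        enc.append((name, ch, 2**i))
        if i < levels - 1:
            L.append(LayerSpec(f"Pool{i + 1}", "pool", [name],
                               out_channels=ch, scale=2 ** (i + 1), block=f"Conv{i + 1}"))
            src = f"Pool{i + 1}"
    src = enc[-1][0]
    for j, (skip, ch, scale) in enumerate(reversed(enc[:-1])):
        up = f"Dec{j + 1}u"
        L.append(LayerSpec(up, "upconv", [src], (3, 3), 1, ch, scale, f"Up{6 + j}"))
        cat = f"Dec{j + 1}c"
        L.append(LayerSpec(cat, "concat", [up, skip], out_channels=2 * ch,
                           scale=scale, block=f"Up{6 + j}"))
        conv = f"Dec{j + 1}"
        L.append(LayerSpec(conv, "conv", [cat], (3, 3), 1, ch, scale, f"Up{6 + j}"))
        src = conv
    L.append(LayerSpec("Out", "output", [src], (1, 1), 1, input_channels, 1, "Up12",
                       options={"activation": "sigmoid"}))
    return ArchTable(layers=L, input_channels=input_channels, spatial_rank=3,
                     pool_z=True, name=f"baseline-unet/{levels}")


# ---------------------------------------------------------------------------
# layer modules
# ---------------------------------------------------------------------------

def _he_init(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class _ConvModule:
    """Conv + optional activation.  kernel/dilation are 3-tuples (z, y, x)."""

    def __init__(self, name, in_ch, out_ch, kernel, dilation, activation, rng):
        self.name = name
        self.kernel = kernel
        self.dilation = dilation
        self.activation = activation
        self.weight = Tensor(_he_init(rng, (out_ch, in_ch) + tuple(kernel)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def params(self):
        return [self.weight, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        out = ag.conv3d(x, self.weight, self.bias, self.dilation)
        if self.activation == "relu":
            return ag.relu(out)
        if self.activation == "sigmoid":
            return ag.sigmoid(out)
        return out


class _DenseBlockModule:
    """1x1 bottleneck, n densely connected convs of growth_rate maps each,
    then a channel-setting 1x1 projection.

    Every internal conv receives the concatenation of the bottleneck output
    and all previous dense outputs; ``layer_inputs`` records that wiring so
    the connectivity is assertable on the graph.
    """

    def __init__(self, name, in_ch, out_ch, kernel, rng, growth_rate=3,
                 n_layers=4, bottleneck=None):
        self.name = name
        self.growth_rate = growth_rate
        self.n_layers = n_layers
        bottleneck = in_ch if bottleneck is None else bottleneck
        self.bottleneck_channels = bottleneck
        self.bottleneck = _ConvModule(
            f"{name}/bottleneck", in_ch, bottleneck, (1, 1, 1), (1, 1, 1), "relu", rng
        )
        self.convs = []
        self.layer_inputs = []
        ch = bottleneck
        for i in range(n_layers):
            self.convs.append(
                _ConvModule(f"{name}/dense{i + 1}", ch, growth_rate, kernel, (1, 1, 1), "relu", rng)
            )
            self.layer_inputs.append(["bottleneck"] + [f"dense{j + 1}" for j in range(i)])
            ch += growth_rate
        self.pre_projection_channels = ch  # bottleneck + n_layers * growth
        self.project = _ConvModule(
            f"{name}/project", ch, out_ch, (1, 1, 1), (1, 1, 1), "relu", rng
        )

    def params(self):
        out = self.bottleneck.params()
        for c in self.convs:
            out += c.params()
        return out + self.project.params()

    def __call__(self, x: Tensor) -> Tensor:
        feats = [self.bottleneck(x)]
        for conv in self.convs:
            inp = feats[0] if len(feats) == 1 else ag.concat(feats)
            feats.append(conv(inp))
        return self.project(ag.concat(feats))


def dense_block(in_channels: int, growth_rate: int = 3, n_layers: int = 4,
                out_channels: Optional[int] = None, kernel=(3, 3, 3),
                rng: Optional[np.random.Generator] = None) -> _DenseBlockModule:
    """Standalone dense-block constructor (growth arithmetic is assertable
    via ``pre_projection_channels`` and ``layer_inputs``)."""
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    rng = rng or np.random.default_rng(0)
    out_channels = out_channels if out_channels is not None else in_channels
    return _DenseBlockModule("dense", in_channels, out_channels, tuple(kernel), rng,
                             growth_rate=growth_rate, n_layers=n_layers)


class _PoolModule:
    def __init__(self, name, pool):
        self.name = name
        self.pool = pool

    def params(self):
        return []

    def __call__(self, x: Tensor) -> Tensor:
        return ag.maxpool3d(x, self.pool)


class _UpConvModule:
    """Resize convolution: conv at the incoming scale, then nearest 2x (or
    1x) upsampling."""

    def __init__(self, name, in_ch, out_ch, kernel, factor, rng):
        self.name = name
        self.factor = factor
        self.conv = _ConvModule(name + "/conv", in_ch, out_ch, kernel, (1, 1, 1), "relu", rng)

    def params(self):
        return self.conv.params()

    def __call__(self, x: Tensor) -> Tensor:
        out = self.conv(x)
        if max(self.factor) > 1:
            out = ag.upsample_nearest(out, self.factor)
        return out


class _ConcatModule:
    def __init__(self, name):
        self.name = name

    def params(self):
        return []

    def __call__(self, xs) -> Tensor:
        return ag.concat(xs)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class Network:
    """A network instantiated from an ArchTable.

    mode '2d' keeps the z axis singleton (kernels and pools do not extend
    into z); mode '3d' extends kernels isotropically and pools z when the
    table's pool_z flag is set.  Dropout (rate settable via set_dropout) is
    applied after the two deepest encoder concat layers.
    """

    def __init__(self, table: ArchTable, mode: str = "3d", seed: int = 0):
        if mode not in ("2d", "3d"):
            raise ValueError(f"mode must be '2d' or '3d', got {mode}")
        self.table = table
        self.mode = mode
        self.dropout_rate = 0.0
        rng = np.random.default_rng(seed)
        self.modules: dict = {}
        self.trainable: dict = {}
        self._out_name = table.layers[-1].name
        self.dropout_after = self._deepest_encoder_concats()

        ch: dict = {}
        for spec in table.layers:
            ch[spec.name] = spec.out_channels
            self.trainable[spec.name] = True
            if spec.kind == "input":
                continue
            in_ch = sum(ch[s] for s in spec.sources)
            kern = self._extend_kernel(spec.kernel)
            if spec.kind in ("conv", "dilated_conv", "output"):
                dil = (1,) + (spec.dilation,) * 2 if mode == "2d" else (
                    (spec.dilation,) * 3 if table.pool_z else (1,) + (spec.dilation,) * 2
                )
                act = spec.options.get("activation", "relu")
                self.modules[spec.name] = _ConvModule(spec.name, in_ch, spec.out_channels,
                                                      kern, dil, act, rng)
            elif spec.kind == "dense_block":
                self.modules[spec.name] = _DenseBlockModule(
                    spec.name, in_ch, spec.out_channels, kern, rng,
                    growth_rate=spec.options.get("growth_rate", 3),
                    n_layers=spec.options.get("n_layers", 4),
                    bottleneck=spec.options.get("bottleneck"),
                )
            elif spec.kind == "pool":
                self.modules[spec.name] = _PoolModule(spec.name, self._pool_factor())
            elif spec.kind == "transition":
                conv = _ConvModule(spec.name + "/conv", in_ch, spec.out_channels,
                                   (1, 1, 1), (1, 1, 1), "relu", rng)
                pool = _PoolModule(spec.name + "/pool", self._pool_factor())
                self.modules[spec.name] = _TransitionModule(spec.name, conv, pool)
            elif spec.kind == "upconv":
                factor = spec.options.get("upsample", 2)
                f = self._pool_factor() if factor == 2 else (1, 1, 1)
                self.modules[spec.name] = _UpConvModule(spec.name, in_ch, spec.out_channels,
                                                        kern, f, rng)
            elif spec.kind == "concat":
                self.modules[spec.name] = _ConcatModule(spec.name)
            else:
                raise TableError(f"unknown layer kind {spec.kind!r} ({spec.name})")

    def _extend_kernel(self, kernel) -> tuple:
        k = tuple(kernel)
        if len(k) == 3:
            return k
        ky, kx = k
        kz = ky if self.mode == "3d" else 1
        return (kz, ky, kx)

    def _pool_factor(self) -> tuple:
        if self.mode == "3d" and self.table.pool_z:
            return (2, 2, 2)
        return (1, 2, 2)

    def _deepest_encoder_concats(self) -> set:
        names = [l.name for l in self.table.layers
                 if l.kind == "concat" and l.name.startswith("Conv")]
        return set(names[-2:])

    # -- parameters -------------------------------------------------------

    def named_params(self):
        """Yield (layer name, parameter tensor) pairs in table order."""
        for spec in self.table.layers:
            mod = self.modules.get(spec.name)
            if mod is None:
                continue
            for p in mod.params():
                yield spec.name, p

    def parameters(self, trainable_only: bool = False):
        return [p for name, p in self.named_params()
                if not trainable_only or self.trainable[name]]

    def set_trainable(self, layer_names) -> None:
        """Freeze every layer not in ``layer_names``."""
        allowed = set(layer_names)
        for spec in self.table.layers:
            self.trainable[spec.name] = spec.name in allowed

    def get_state(self):
        return [p.data.copy() for _, p in self.named_params()]

    def set_state(self, state) -> None:
        params = [p for _, p in self.named_params()]
        if len(state) != len(params):
            raise ValueError("state length mismatch")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError("state shape mismatch")
            p.data = np.ascontiguousarray(s, dtype=np.float32)

    def set_dropout(self, rate: float) -> None:
        self.dropout_rate = float(rate)

    # -- forward ----------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> Tensor:
        """Run a batch (N, C, D, H, W) through the network; returns the
        output probability tensor."""
        acts = self.forward_all(x, training=training, rng=rng)
        return acts[self._out_name]

    def forward_all(self, x: np.ndarray, training: bool = False,
                    rng: Optional[np.random.Generator] = None) -> dict:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 5:
            raise ValueError("input must be (N, C, D, H, W)")
        rng = rng or np.random.default_rng(0)
        acts: dict = {}
        for spec in self.table.layers:
            if spec.kind == "input":
                acts[spec.name] = Tensor(x)
                continue
            mod = self.modules[spec.name]
            if spec.kind == "concat":
                out = mod([acts[s] for s in spec.sources])
            else:
                out = mod(acts[spec.sources[0]])
            if spec.name in self.dropout_after and self.dropout_rate > 0:
                out = ag.dropout(out, self.dropout_rate, rng, training)
            acts[spec.name] = out
        return acts


class _TransitionModule:
    def __init__(self, name, conv, pool):
        self.name = name
        self.conv = conv
        self.pool = pool

    def params(self):
        return self.conv.params()

    def __call__(self, x: Tensor) -> Tensor:
        return self.pool(self.conv(x))


# ---------------------------------------------------------------------------
# public builders / tracer
# ---------------------------------------------------------------------------

def build_network(table: ArchTable, mode: str = "3d", seed: int = 0) -> Network:
    """Instantiate trainable layers from a validated table."""
    table.validate()
    return Network(table, mode=mode, seed=seed)


def build_baseline_unet(levels: int = 3, base_channels: int = 32, mode: str = "3d",
                        input_channels: int = 1, seed: int = 0) -> Network:
    return build_network(baseline_unet_table(levels, base_channels, input_channels),
                         mode=mode, seed=seed)


def shape_trace(network: Network | ArchTable, input_dims: Sequence[int],
                mode: Optional[str] = None) -> ShapeTrace:
    """Symbolic (spatial dims, channels) trace of every named layer.

    input_dims is (H, W) in 2d mode or (D, H, W) in 3d mode.  In-plane dims
    must be divisible by the cumulative pooling factor; the error message
    suggests the nearest valid size.
    """
    if isinstance(network, ArchTable):
        table = network
        mode = mode or ("2d" if len(input_dims) == 2 else "3d")
        pool_z = table.pool_z and mode == "3d"
    else:
        table = network.table
        mode = mode or network.mode
        pool_z = table.pool_z and mode == "3d"

    dims = tuple(int(v) for v in input_dims)
    if mode == "2d":
        if len(dims) != 2:
            raise ValueError("2d mode expects (H, W) input dims")
        d0, (h0, w0) = 1, dims
    else:
        if len(dims) != 3:
            raise ValueError("3d mode expects (D, H, W) input dims")
        d0, h0, w0 = dims

    factor = table.max_scale()
    for v, label in ((h0, "H"), (w0, "W")) + (((d0, "D"),) if pool_z else ()):
        if v % factor:
            nearest = max(round(v / factor), 1) * factor
            raise ValueError(
                f"{label}={v} not divisible by the cumulative pooling factor "
                f"{factor}; nearest valid size is {nearest}"
            )

    records = []
    for spec in table.layers:
        s = spec.scale
        dz = d0 // s if pool_z else d0
        spatial = (h0 // s, w0 // s) if mode == "2d" else (dz, h0 // s, w0 // s)
        records.append((spec.name, spatial, spec.out_channels))
    return ShapeTrace(records=records)


def count_params(network: Network, trainable_only: bool = False) -> int:
    """Exact count of (optionally only trainable) parameter scalars."""
    return int(sum(p.data.size for p in network.parameters(trainable_only=trainable_only)))
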