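"""The Fus2Net architecture: declarative layer table, shape inference,
network builder, and table conformance checking.

Fus2Net is a multi-branch fusion CNN for two-class breast-ultrasound images:
a three-convolution stem, Block 1 (three two-branch fusion modules whose
branch outputs are channel-concatenated), Block 2 (three convolutional
branches concatenated, projected by a 1x1 convolution, multiplied by a small
residual scale and added back to the block input), and a two-layer dense
classifier head.

Two independent routes to every layer shape exist here on purpose:

* :func:`infer_shape` — closed-form output-shape arithmetic over a
  :class:`LayerSpec` (valid: floor((n-f)/s)+1; same: ceil(n/s));
* the built network itself, whose actual tensor shapes are recorded by
  running a forward pass.

:func:`conformance_check` compares the built network row-by-row against
:func:`reference_table`, which encodes the published 299x299 layer table
(with three printed inconsistencies corrected and flagged, see the table
row notes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from . import nn


class TensorShape(NamedTuple):
    height: int
    width: int
    channels: int


@dataclass
class LayerSpec:
    """One declarative row: layer kind plus its geometry."""

    name: str
    kind: str  # conv | maxpool | avgpool | concat | add | input
    filter_size: tuple[int, int] | None = None
    stride: tuple[int, int] | None = None
    padding: str = "valid"
    out_channels: int | None = None
    inputs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind in ("conv", "maxpool", "avgpool"):
            if self.filter_size is None or self.stride is None:
                raise ValueError(f"{self.kind} layer {self.name!r} needs filter and stride")
        if self.kind in ("concat", "add") and len(self.inputs) < 2:
            raise ValueError(f"{self.kind} layer {self.name!r} needs >= 2 inputs")


@dataclass
class TableRow:
    index: int
    spec: LayerSpec
    expected_in: list[TensorShape]
    expected_out: TensorShape
    note: str = ""


@dataclass
class ArchitectureTable:
    rows: list[TableRow]

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, name: str) -> TableRow:
        for r in self.rows:
            if r.spec.name == name:
                return r
        raise KeyError(name)


def infer_shape(spec: LayerSpec, in_shapes: list[TensorShape]) -> TensorShape:
    """Closed-form output shape of one layer — the oracle for the table.

    valid padding: floor((n - f) / s) + 1; same padding: ceil(n / s).
    Concatenation sums channels and requires equal spatial dims; addition
    requires identical shapes.
    """
    kind = spec.kind
    if kind == "input":
        (s,) = in_shapes
        return s
    if kind in ("conv", "maxpool", "avgpool"):
        (s,) = in_shapes
        fh, fw = spec.filter_size
        sh, sw = spec.stride
        if spec.padding == "valid":
            h = (s.height - fh) // sh + 1
            w = (s.width - fw) // sw + 1
            if h < 1 or w < 1:
                raise ValueError(f"{spec.name}: window {fh}x{fw} exceeds input {s}")
        elif spec.padding == "same":
            h = -(-s.height // sh)
            w = -(-s.width // sw)
        else:
            raise ValueError(f"unknown padding {spec.padding!r}")
        c = spec.out_channels if kind == "conv" else s.channels
        return TensorShape(h, w, c)
    if kind == "concat":
        spatial = {(s.height, s.width) for s in in_shapes}
        if len(spatial) != 1:
            raise ValueError(f"{spec.name}: concat inputs differ spatially {sorted(spatial)}")
        h, w = spatial.pop()
        return TensorShape(h, w, sum(s.channels for s in in_shapes))
    if kind == "add":
        if len(set(in_shapes)) != 1:
            raise ValueError(f"{spec.name}: add inputs differ {in_shapes}")
        return in_shapes[0]
    raise ValueError(f"infer_shape does not cover kind {spec.kind!r}")


# --------------------------------------------------------------------------
# Reference table (299 x 299 x 3 input)
# --------------------------------------------------------------------------

_ERRATUM_IN_CH = (
    "input channel count printed as 3; read as the preceding layer's output"
)
_ERRATUM_MODULE = "heading printed 'Block 1 module 2'; read as module 3"
_ERRATUM_POOL = (
    "printed with no filter size and strides (1,1), which cannot map 35 -> 4; "
    "implemented as 8x8 pool, stride 8, valid"
)


def reference_table() -> ArchitectureTable:
    """The published 27-row layer table for the 299x299x3 input.

    Rows whose printed cells are internally inconsistent carry a ``note``
    describing the correction applied (chosen so the printed output shapes
    are reproduced exactly).
    """

    def S(h, w, c):
        return TensorShape(h, w, c)

    rows: list[TableRow] = []

    def add(index, spec, ins, out, note=""):
        rows.append(TableRow(index, spec, ins, out, note))

    add(1, LayerSpec("Input_Layer", "input", inputs=[]), [S(299, 299, 3)], S(299, 299, 3))
    add(2, LayerSpec("Conv2d_1", "conv", (3, 3), (2, 2), "valid", 32, ["Input_Layer"]),
        [S(299, 299, 3)], S(149, 149, 32))
    add(3, LayerSpec("Conv2d_2", "conv", (3, 3), (1, 1), "valid", 32, ["Conv2d_1"]),
        [S(149, 149, 32)], S(147, 147, 32), _ERRATUM_IN_CH)
    add(4, LayerSpec("Conv2d_3", "conv", (3, 3), (1, 1), "same", 64, ["Conv2d_2"]),
        [S(147, 147, 32)], S(147, 147, 64), _ERRATUM_IN_CH)
    # Block 1 module 1: max-pool branch || 3x3 stride-2 conv branch
    add(5, LayerSpec("Max_pooling2d", "maxpool", (3, 3), (2, 2), "valid", None, ["Conv2d_3"]),
        [S(147, 147, 64)], S(73, 73, 64))
    add(6, LayerSpec("Conv2d_4", "conv", (3, 3), (2, 2), "valid", 96, ["Conv2d_3"]),
        [S(147, 147, 64)], S(73, 73, 96))
    add(7, LayerSpec("Concatenate_1", "concat", inputs=["Max_pooling2d", "Conv2d_4"]),
        [S(73, 73, 64), S(73, 73, 96)], S(73, 73, 160))
    # Block 1 module 2: two conv branches
    add(8, LayerSpec("Conv2d_5", "conv", (1, 1), (1, 1), "same", 64, ["Concatenate_1"]),
        [S(73, 73, 160)], S(73, 73, 64))
    add(9, LayerSpec("Conv2d_6", "conv", (3, 3), (1, 1), "valid", 96, ["Conv2d_5"]),
        [S(73, 73, 64)], S(71, 71, 96))
    add(10, LayerSpec("Conv2d_7", "conv", (1, 1), (1, 1), "same", 64, ["Concatenate_1"]),
        [S(73, 73, 160)], S(73, 73, 64))
    add(11, LayerSpec("Conv2d_8", "conv", (7, 1), (1, 1), "same", 64, ["Conv2d_7"]),
        [S(73, 73, 64)], S(73, 73, 64))
    add(12, LayerSpec("Conv2d_9", "conv", (1, 7), (1, 1), "same", 64, ["Conv2d_8"]),
        [S(73, 73, 64)], S(73, 73, 64))
    add(13, LayerSpec("Conv2d_10", "conv", (3, 3), (1, 1), "valid", 96, ["Conv2d_9"]),
        [S(73, 73, 64)], S(71, 71, 96))
    add(14, LayerSpec("Concatenate_2", "concat", inputs=["Conv2d_6", "Conv2d_10"]),
        [S(71, 71, 96), S(71, 71, 96)], S(71, 71, 192))
    # Block 1 module 3: average-pool branch || 3x3 stride-2 conv branch
    add(15, LayerSpec("Average_pooling2d", "avgpool", (3, 3), (2, 2), "valid", None,
                      ["Concatenate_2"]),
        [S(71, 71, 192)], S(35, 35, 192), _ERRATUM_MODULE)
    add(16, LayerSpec("Conv2d_11", "conv", (3, 3), (2, 2), "valid", 192, ["Concatenate_2"]),
        [S(71, 71, 192)], S(35, 35, 192), _ERRATUM_MODULE)
    add(17, LayerSpec("Concatenate_3", "concat", inputs=["Average_pooling2d", "Conv2d_11"]),
        [S(35, 35, 192), S(35, 35, 192)], S(35, 35, 384), _ERRATUM_MODULE)
    # Block 2: three conv branches -> concat -> 1x1 projection -> scaled add
    add(18, LayerSpec("Conv2d_12", "conv", (1, 1), (1, 1), "same", 32, ["Concatenate_3"]),
        [S(35, 35, 384)], S(35, 35, 32))
    add(19, LayerSpec("Conv2d_13", "conv", (1, 1), (1, 1), "same", 32, ["Concatenate_3"]),
        [S(35, 35, 384)], S(35, 35, 32))
    add(20, LayerSpec("Conv2d_14", "conv", (3, 3), (1, 1), "same", 32, ["Conv2d_13"]),
        [S(35, 35, 32)], S(35, 35, 32))
    add(21, LayerSpec("Conv2d_15", "conv", (1, 1), (1, 1), "same", 32, ["Concatenate_3"]),
        [S(35, 35, 384)], S(35, 35, 32))
    add(22, LayerSpec("Conv2d_16", "conv", (3, 3), (1, 1), "same", 48, ["Conv2d_15"]),
        [S(35, 35, 32)], S(35, 35, 48))
    add(23, LayerSpec("Conv2d_17", "conv", (3, 3), (1, 1), "same", 64, ["Conv2d_16"]),
        [S(35, 35, 48)], S(35, 35, 64))
    add(24, LayerSpec("Concatenate_4", "concat",
                      inputs=["Conv2d_12", "Conv2d_14", "Conv2d_17"]),
        [S(35, 35, 32), S(35, 35, 32), S(35, 35, 64)], S(35, 35, 128))
    add(25, LayerSpec("Conv2d_18", "conv", (1, 1), (1, 1), "same", 384, ["Concatenate_4"]),
        [S(35, 35, 128)], S(35, 35, 384))
    add(26, LayerSpec("Add", "add", inputs=["Conv2d_18", "Concatenate_3"]),
        [S(35, 35, 384), S(35, 35, 384)], S(35, 35, 384))
    add(27, LayerSpec("Average_pooling2d_1", "avgpool", (8, 8), (8, 8), "valid", None,
                      ["Add"]),
        [S(35, 35, 384)], S(4, 4, 384), _ERRATUM_POOL)
    return ArchitectureTable(rows)


# --------------------------------------------------------------------------
# Builder
# --------------------------------------------------------------------------


@dataclass
class Fus2NetConfig:
    """Tunable architecture hyperparameters.

    ``input_size`` other than 299 yields the same topology at a reduced
    (or enlarged) resolution; the head pooling window is then chosen as
    ``final_spatial // 4`` so the pooled map stays close to 4x4.
    """

    input_size: int = 299
    channels: int = 3
    residual_scale: float = 0.1
    fc1_width: int = 128
    dropout_rate: float = 0.5
    l2_factor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l2_factor < 0:
            raise ValueError("l2_factor must be non-negative")
        if not 0.0 < self.residual_scale <= 1.0:
            raise ValueError("residual_scale must be in (0, 1]")
        if self.input_size < 32:
            raise ValueError("input_size must be >= 32 for the topology to close")


@dataclass
class ModelHandle:
    """A built network plus the registry used for conformance checking.

    ``registry`` maps each reference-table layer name to its actual input
    shapes, output shape and parameter count (convolution rows include the
    batch-norm that follows them).
    """

    network: nn.Network
    config: Fus2NetConfig
    registry: dict[str, dict] = field(default_factory=dict)

    @property
    def residual_scale(self) -> float:
        return self.config.residual_scale

    @property
    def fc1_width(self) -> int:
        return self.config.fc1_width

    @property
    def dropout_rate(self) -> float:
        return self.config.dropout_rate

    @property
    def l2_factor(self) -> float:
        return self.config.l2_factor

    def param_count(self) -> int:
        return self.network.param_count()


class _Builder:
    def __init__(self, cfg: Fus2NetConfig):
        self.cfg = cfg
        self.net = nn.Network()
        self.rng = np.random.default_rng(cfg.seed)
        #: table-row name -> name of the network node carrying that row's output
        self.row_nodes: dict[str, str] = {}
        #: table-row name -> extra layers counted with the row (batch norms)
        self.row_extras: dict[str, list[str]] = {}

    def conv_unit(
        self, name, src, cin, cout, kernel, stride=1, padding="valid", bn_relu=True
    ) -> str:
        self.net.add(
            name,
            nn.Conv2D(cin, cout, kernel, stride, padding, rng=self.rng),
            src,
        )
        out = name
        extras = []
        if bn_relu:
            self.net.add(f"{name}_bn", nn.BatchNorm(cout), out)
            self.net.add(f"{name}_relu", nn.ReLU(), f"{name}_bn")
            out = f"{name}_relu"
            extras.append(f"{name}_bn")
        self.row_nodes[name] = name
        self.row_extras[name] = extras
        return out


def build_stem(builder: _Builder) -> str:
    """Three stem convolutions: 3x3/s2 valid, 3x3/s1 valid, 3x3/s1 same."""
    c = builder.cfg.channels
    x = builder.conv_unit("Conv2d_1", nn.INPUT, c, 32, 3, 2, "valid")
    x = builder.conv_unit("Conv2d_2", x, 32, 32, 3, 1, "valid")
    x = builder.conv_unit("Conv2d_3", x, 32, 64, 3, 1, "same")
    return x


def build_block1(builder: _Builder, stem_out: str) -> str:
    """Three two-branch fusion modules, each ending in a concatenation."""
    net = builder.net
    # Module 1: max-pool branch || 96-filter stride-2 conv branch
    net.add("Max_pooling2d", nn.MaxPool2D(3, 2), stem_out)
    builder.row_nodes["Max_pooling2d"] = "Max_pooling2d"
    conv4 = builder.conv_unit("Conv2d_4", stem_out, 64, 96, 3, 2, "valid")
    net.add("Concatenate_1", nn.Concat(), ["Max_pooling2d", conv4])
    builder.row_nodes["Concatenate_1"] = "Concatenate_1"
    # Module 2: {1x1; 3x3 valid} || {1x1; 7x1; 1x7; 3x3 valid}
    a = builder.conv_unit("Conv2d_5", "Concatenate_1", 160, 64, 1, 1, "same")
    a = builder.conv_unit("Conv2d_6", a, 64, 96, 3, 1, "valid")
    b = builder.conv_unit("Conv2d_7", "Concatenate_1", 160, 64, 1, 1, "same")
    b = builder.conv_unit("Conv2d_8", b, 64, 64, (7, 1), 1, "same")
    b = builder.conv_unit("Conv2d_9", b, 64, 64, (1, 7), 1, "same")
    b = builder.conv_unit("Conv2d_10", b, 64, 96, 3, 1, "valid")
    net.add("Concatenate_2", nn.Concat(), [a, b])
    builder.row_nodes["Concatenate_2"] = "Concatenate_2"
    # Module 3: average-pool branch || 192-filter stride-2 conv branch
    net.add("Average_pooling2d", nn.AvgPool2D(3, 2), "Concatenate_2")
    builder.row_nodes["Average_pooling2d"] = "Average_pooling2d"
    conv11 = builder.conv_unit("Conv2d_11", "Concatenate_2", 192, 192, 3, 2, "valid")
    net.add("Concatenate_3", nn.Concat(), ["Average_pooling2d", conv11])
    builder.row_nodes["Concatenate_3"] = "Concatenate_3"
    return "Concatenate_3"


def build_block2(builder: _Builder, block1_out: str) -> str:
    """Three conv branches -> concat -> 1x1 projection -> scaled residual add."""
    net = builder.net
    b1 = builder.conv_unit("Conv2d_12", block1_out, 384, 32, 1, 1, "same")
    b2 = builder.conv_unit("Conv2d_13", block1_out, 384, 32, 1, 1, "same")
    b2 = builder.conv_unit("Conv2d_14", b2, 32, 32, 3, 1, "same")
    b3 = builder.conv_unit("Conv2d_15", block1_out, 384, 32, 1, 1, "same")
    b3 = builder.conv_unit("Conv2d_16", b3, 32, 48, 3, 1, "same")
    b3 = builder.conv_unit("Conv2d_17", b3, 48, 64, 3, 1, "same")
    net.add("Concatenate_4", nn.Concat(), [b1, b2, b3])
    builder.row_nodes["Concatenate_4"] = "Concatenate_4"
    # linear 1x1 projection back to the trunk width, no activation before add
    proj = builder.conv_unit("Conv2d_18", "Concatenate_4", 128, 384, 1, 1, "same",
                             bn_relu=False)
    net.add("residual_scale", nn.Scale(builder.cfg.residual_scale), proj)
    net.add("Add", nn.Add(), ["residual_scale", block1_out])
    builder.row_nodes["Add"] = "Add"
    net.add("post_add_bn", nn.BatchNorm(384), "Add")
    net.add("post_add_relu", nn.ReLU(), "post_add_bn")
    return "post_add_relu"


def build_head(builder: _Builder, trunk_out: str, final_spatial: int) -> str:
    """Average pool -> flatten -> dense(fc1, L2) -> dropout -> dense(2)."""
    cfg = builder.cfg
    net = builder.net
    pool = max(1, final_spatial // 4)
    net.add("Average_pooling2d_1", nn.AvgPool2D(pool, pool), trunk_out)
    builder.row_nodes["Average_pooling2d_1"] = "Average_pooling2d_1"
    pooled = (final_spatial - pool) // pool + 1
    flat_len = pooled * pooled * 384
    net.add("flatten", nn.Flatten(), "Average_pooling2d_1")
    net.add("fc1", nn.Dense(flat_len, cfg.fc1_width, l2=cfg.l2_factor, rng=builder.rng),
            "flatten")
    net.add("fc1_relu", nn.ReLU(), "fc1")
    net.add("dropout", nn.Dropout(cfg.dropout_rate, seed=cfg.seed), "fc1_relu")
    net.add("logits", nn.Dense(cfg.fc1_width, 2, rng=builder.rng), "dropout")
    return "logits"


def _final_spatial(input_size: int) -> int:
    n = input_size
    n = (n - 3) // 2 + 1      # Conv2d_1
    n = n - 2                 # Conv2d_2
    n = (n - 3) // 2 + 1      # module 1
    n = n - 2                 # module 2 (3x3 valid)
    n = (n - 3) // 2 + 1      # module 3
    return n


def build_fus2net(cfg: Fus2NetConfig | None = None) -> ModelHandle:
    """Build the full network and record its shape registry.

    The registry is filled by pushing a single zero image through the built
    network and reading off every node's actual input/output shapes — an
    execution-level check independent of :func:`infer_shape`.
    """
    cfg = cfg or Fus2NetConfig()
    builder = _Builder(cfg)
    x = build_stem(builder)
    x = build_block1(builder, x)
    x = build_block2(builder, x)
    build_head(builder, x, _final_spatial(cfg.input_size))
    handle = ModelHandle(network=builder.net, config=cfg)
    _record_registry(handle, builder)
    return handle


def _record_registry(handle: ModelHandle, builder: _Builder) -> None:
    net = handle.network
    cfg = handle.config
    dummy = np.zeros((1, cfg.input_size, cfg.input_size, cfg.channels), dtype=np.float32)
    cache: dict[str, np.ndarray] = {nn.INPUT: dummy}
    shapes: dict[str, tuple] = {nn.INPUT: dummy.shape}
    for node in net.nodes:
        ins = [cache[s] for s in node.inputs]
        out = node.layer.forward(ins, training=False)
        cache[node.name] = out
        shapes[node.name] = out.shape

    def ts(shape) -> TensorShape:
        return TensorShape(*shape[1:])

    registry: dict[str, dict] = {
        "Input_Layer": {
            "in_shapes": [ts(dummy.shape)],
            "out_shape": ts(dummy.shape),
            "params": 0,
        }
    }
    by_name = {n.name: n for n in net.nodes}
    for row_name, node_name in builder.row_nodes.items():
        node = by_name[node_name]
        in_shapes = [ts(shapes[s]) for s in node.inputs]
        params = node.layer.param_count()
        for extra in builder.row_extras.get(row_name, []):
            params += by_name[extra].layer.param_count()
        registry[row_name] = {
            "in_shapes": in_shapes,
            "out_shape": ts(shapes[node_name]),
            "params": params,
        }
    handle.registry = registry


# --------------------------------------------------------------------------
# Conformance
# --------------------------------------------------------------------------


@dataclass
class RowOutcome:
    name: str
    match: bool
    expected: TensorShape | None
    actual: TensorShape | None
    detail: str = ""


@dataclass
class ConformanceReport:
    outcomes: list[RowOutcome]
    total_params: int

    @property
    def mismatches(self) -> list[RowOutcome]:
        return [o for o in self.outcomes if not o.match]

    @property
    def passed(self) -> bool:
        return not self.mismatches

    def to_dict(self) -> dict:
        return {
            "pass": self.passed,
            "total_params": self.total_params,
            "rows": [
                {
                    "name": o.name,
                    "match": o.match,
                    "expected": list(o.expected) if o.expected else None,
                    "actual": list(o.actual) if o.actual else None,
                    "detail": o.detail,
                }
                for o in self.outcomes
            ],
        }


def conformance_check(model: ModelHandle, table: ArchitectureTable) -> ConformanceReport:
    """Compare the built model's recorded shapes against a reference table.

    Every row is compared on its output shape and (order-insensitively) its
    input shapes; a missing layer is reported as a mismatch entry rather
    than raised.
    """
    outcomes = []
    for row in table:
        entry = model.registry.get(row.spec.name)
        if entry is None:
            outcomes.append(
                RowOutcome(row.spec.name, False, row.expected_out, None, "layer missing")
            )
            continue
        ok = entry["out_shape"] == row.expected_out and sorted(
            entry["in_shapes"]
        ) == sorted(row.expected_in)
        detail = "" if ok else (
            f"expected in={row.expected_in} out={row.expected_out}, "
            f"got in={entry['in_shapes']} out={entry['out_shape']}"
        )
        outcomes.append(
            RowOutcome(row.spec.name, ok, row.expected_out, entry["out_shape"], detail)
        )
    return ConformanceReport(outcomes, model.param_count())


def forward(model: ModelHandle, batch: np.ndarray) -> np.ndarray:
    """Inference-mode class probabilities, shape (n, 2), rows summing to 1."""
    batch = np.asarray(batch)
    cfg = model.config
    expected = (cfg.input_size, cfg.input_size, cfg.channels)
    if batch.ndim != 4 or batch.shape[1:] != expected:
        raise ValueError(f"batch must be (n, {expected[0]}, {expected[1]}, {expected[2]}), "
                         f"got {batch.shape}")
    return model.network.predict_proba(batch)
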