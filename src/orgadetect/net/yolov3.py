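"""CBAM-YOLOv3: Darknet-53-style residual backbone, three-scale FPN head,
optional convolutional block attention after each backbone stage.

The network takes 416x416x3 input (grayscale images are replicated to three
channels upstream) and predicts, at strides 32/16/8, three anchors per cell
with ``5 + num_classes`` channels each: box offsets ``t_x, t_y, t_w, t_h``,
an objectness logit and per-class logits. ``width_multiplier`` scales every
channel count so the same architecture trains at desk scale on CPU.

Box decoding follows the standard parameterisation: with cell origin
``(c_x, c_y)`` and anchor prior ``(p_w, p_h)``,

    b_x = (sigmoid(t_x) + c_x) * stride      b_w = p_w * exp(t_w)
    b_y = (sigmoid(t_y) + c_y) * stride      b_h = p_h * exp(t_h)

and a detection's confidence is sigmoid(objectness) * sigmoid(class logit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ..boxes import BoundingBox
from .cbam import CBAM
from .layers import Add, Concat, Conv2d, ConvBNLeaky, Layer, Param, Upsample2x, sigmoid

__all__ = ["AnchorSet", "YoloV3", "build_detector", "decode_boxes", "DEFAULT_ANCHORS"]

STRIDES = (32, 16, 8)

#: Fallback anchor priors (pixels on the 416 input frame), ascending by area;
#: production models re-estimate them from the training boxes.
DEFAULT_ANCHORS = (
    (20, 20), (32, 32, ), (45, 45),
    (60, 60), (75, 75), (90, 90),
    (110, 110), (140, 140), (180, 180),
)


@dataclass(frozen=True)
class AnchorSet:
    """Nine (w, h) anchor priors sorted ascending by area, three per scale.

    Scale 0 (stride 32) takes the three largest, scale 2 (stride 8) the three
    smallest, following the usual coarse-to-fine assignment.
    """

    anchors: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.anchors) != 9:
            raise ValueError("AnchorSet needs exactly 9 anchors")
        areas = [w * h for w, h in self.anchors]
        if any(w <= 0 or h <= 0 for w, h in self.anchors):
            raise ValueError("anchor dimensions must be positive")
        if any(a > b + 1e-9 for a, b in zip(areas, areas[1:])):
            raise ValueError("anchors must be sorted ascending by area")

    def for_scale(self, scale_idx: int) -> tuple[tuple[float, float], ...]:
        start = (2 - scale_idx) * 3  # stride 32 -> anchors 6..8
        return self.anchors[start : start + 3]


class _Graph:
    """A static single-output DAG of layers, executed forward and reverse."""

    INPUT = -1

    def __init__(self):
        self.layers: list[Layer] = []
        self.inputs: list[tuple[int, ...]] = []

    def add(self, layer: Layer, *inputs: int) -> int:
        self.layers.append(layer)
        self.inputs.append(inputs if inputs else (len(self.layers) - 2,))
        return len(self.layers) - 1

    def forward(self, x: np.ndarray, train: bool) -> list[np.ndarray]:
        outs: list[np.ndarray] = []
        for layer, inp in zip(self.layers, self.inputs):
            args = [x if i == self.INPUT else outs[i] for i in inp]
            outs.append(layer.forward(*args, train=train))
        return outs

    def backward(self, seed_grads: dict[int, np.ndarray]) -> None:
        grads: dict[int, np.ndarray] = {k: v.copy() for k, v in seed_grads.items()}
        for idx in range(len(self.layers) - 1, -1, -1):
            g = grads.pop(idx, None)
            if g is None:
                continue
            dins = self.layers[idx].backward(g)
            for src, dg in zip(self.inputs[idx], dins):
                if src == self.INPUT:
                    continue
                if src in grads:
                    grads[src] += dg
                else:
                    grads[src] = dg


class YoloV3:
    """The detector. Build via :func:`build_detector`."""

    def __init__(
        self,
        num_classes: int,
        width_multiplier: float = 1.0,
        attention: str = "cbam",
        stage_blocks: tuple[int, ...] = (1, 2, 8, 8, 4),
        reduction_ratio: int = 16,
        input_size: int = 416,
        seed: int = 0,
    ):
        if num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if not (0.0 < width_multiplier <= 1.0):
            raise ValueError("width_multiplier must lie in (0, 1]")
        if attention not in ("cbam", "none"):
            raise ValueError("attention must be 'cbam' or 'none'")
        if input_size % 32 != 0:
            raise ValueError(f"input size {input_size} not divisible by 32")
        self.num_classes = num_classes
        self.width_multiplier = width_multiplier
        self.attention = attention
        self.stage_blocks = tuple(stage_blocks)
        self.reduction_ratio = reduction_ratio
        self.input_size = input_size
        self.seed = seed
        self.anchors = AnchorSet(DEFAULT_ANCHORS)
        rng = np.random.default_rng(seed)

        def ch(base: int) -> int:
            return max(4, int(round(base * width_multiplier)))

        g = _Graph()
        self.graph = g
        per_anchor = 5 + num_classes
        out_ch = 3 * per_anchor

        def cbl(cin, cout, k, stride, name, after):
            return g.add(ConvBNLeaky(cin, cout, k, stride, name=name, rng=rng), after)

        def residual(c, name, after):
            mid = max(2, c // 2)
            a = cbl(c, mid, 1, 1, f"{name}.reduce", after)
            b = cbl(mid, c, 3, 1, f"{name}.expand", a)
            return g.add(Add(), after, b)

        # ---- backbone ----
        node = g.add(ConvBNLeaky(3, ch(32), 3, 1, name="stem", rng=rng), _Graph.INPUT)
        stage_out: dict[int, int] = {}
        cin = ch(32)
        for si, nblocks in enumerate(self.stage_blocks, start=1):
            cout = ch(32 * 2**si)
            node = cbl(cin, cout, 3, 2, f"stage{si}.down", node)
            for bi in range(nblocks):
                node = residual(cout, f"stage{si}.res{bi}", node)
            if attention == "cbam":
                node = g.add(
                    CBAM(cout, reduction_ratio, name=f"stage{si}.cbam", rng=rng), node
                )
            stage_out[si] = node
            cin = cout

        # ---- head ----
        def head_block(cin_, c, name, after):
            n = cbl(cin_, c, 1, 1, f"{name}.conv0", after)
            n = cbl(c, 2 * c, 3, 1, f"{name}.conv1", n)
            n = cbl(2 * c, c, 1, 1, f"{name}.conv2", n)
            n = cbl(c, 2 * c, 3, 1, f"{name}.conv3", n)
            n = cbl(2 * c, c, 1, 1, f"{name}.conv4", n)
            return n

        def head_out(c, name, after):
            n = cbl(c, 2 * c, 3, 1, f"{name}.pre", after)
            # objectness bias starts negative: rare-object prior stabilises
            # early training
            conv = Conv2d(2 * c, out_ch, 1, bias=True, name=f"{name}.out", rng=rng)
            conv.b.data.reshape(3, per_anchor)[:, 4] = -2.0
            return g.add(conv, n)

        c5 = ch(512)
        t5 = head_block(ch(1024), c5, "head32", stage_out[5])
        p5 = head_out(c5, "head32", t5)

        c4 = ch(256)
        r4 = cbl(c5, c4, 1, 1, "route16.conv", t5)
        u4 = g.add(Upsample2x(), r4)
        m4 = g.add(Concat(), u4, stage_out[4])
        t4 = head_block(c4 + ch(512), c4, "head16", m4)
        p4 = head_out(c4, "head16", t4)

        c3 = ch(128)
        r3 = cbl(c4, c3, 1, 1, "route8.conv", t4)
        u3 = g.add(Upsample2x(), r3)
        m3 = g.add(Concat(), u3, stage_out[3])
        t3 = head_block(c3 + ch(256), c3, "head8", m3)
        p3 = head_out(c3, "head8", t3)

        self._out_nodes = (p5, p4, p3)  # strides 32, 16, 8
        self.dtype = np.float32

    def set_dtype(self, dtype) -> None:
        """Switch compute precision (float64 is used for gradient audits)."""
        self.dtype = dtype
        for p in self.parameters():
            p.data = p.data.astype(dtype)
            p.grad = p.grad.astype(dtype)

    # -- parameters --------------------------------------------------------
    def parameters(self) -> list[Param]:
        return [p for layer in self.graph.layers for p in layer.params()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def attention_blocks(self) -> list[CBAM]:
        return [l for l in self.graph.layers if isinstance(l, CBAM)]

    # -- execution ---------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> list[np.ndarray]:
        """Run the network; returns raw predictions per scale, each shaped
        (N, 3, grid_y, grid_x, 5 + num_classes)."""
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got {x.shape}")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("input spatial size must be divisible by 32")
        outs = self.graph.forward(np.ascontiguousarray(x, dtype=self.dtype), train)
        self._last_outs = outs if train else None
        raws = []
        for node in self._out_nodes:
            y = outs[node]
            n, _, gy, gx = y.shape
            raws.append(
                y.reshape(n, 3, 5 + self.num_classes, gy, gx).transpose(0, 1, 3, 4, 2)
            )
        return raws

    def backward(self, raw_grads: Sequence[np.ndarray]) -> None:
        """Backpropagate gradients given per-scale gradients of the raw
        predictions (same layout as :meth:`forward` output)."""
        seeds = {}
        for node, g in zip(self._out_nodes, raw_grads):
            n, _, gy, gx, pa = g.shape
            seeds[node] = np.ascontiguousarray(
                g.transpose(0, 1, 4, 2, 3).reshape(n, 3 * pa, gy, gx), dtype=self.dtype
            )
        self.graph.backward(seeds)
        self._last_outs = None

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- persistence -------------------------------------------------------
    def config(self) -> dict:
        return {
            "num_classes": self.num_classes,
            "width_multiplier": self.width_multiplier,
            "attention": self.attention,
            "stage_blocks": list(self.stage_blocks),
            "reduction_ratio": self.reduction_ratio,
            "input_size": self.input_size,
            "seed": self.seed,
            "anchors": [list(a) for a in self.anchors.anchors],
        }

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {}
        for i, p in enumerate(self.parameters()):
            arrays[f"param_{i:04d}_{p.name}"] = p.data
        for i, layer in enumerate(self.graph.layers):
            bn = getattr(layer, "bn", layer)
            if hasattr(bn, "running_mean"):
                arrays[f"bnstat_{i:04d}_mean"] = bn.running_mean
                arrays[f"bnstat_{i:04d}_var"] = bn.running_var
        return arrays

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: npz of weights with the config embedded."""
        arrays = self.state_arrays()
        arrays["__config__"] = np.frombuffer(
            json.dumps(self.config()).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    def load_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data[...] = arrays[f"param_{i:04d}_{p.name}"]
        for i, layer in enumerate(self.graph.layers):
            bn = getattr(layer, "bn", layer)
            if hasattr(bn, "running_mean"):
                bn.running_mean = arrays[f"bnstat_{i:04d}_mean"].astype(np.float32)
                bn.running_var = arrays[f"bnstat_{i:04d}_var"].astype(np.float32)

    @classmethod
    def load(cls, path: str | Path) -> "YoloV3":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            model = cls(
                num_classes=cfg["num_classes"],
                width_multiplier=cfg["width_multiplier"],
                attention=cfg["attention"],
                stage_blocks=tuple(cfg["stage_blocks"]),
                reduction_ratio=cfg["reduction_ratio"],
                input_size=cfg["input_size"],
                seed=cfg["seed"],
            )
            model.anchors = AnchorSet(tuple(tuple(a) for a in cfg["anchors"]))
            model.load_arrays({k: data[k] for k in data.files if k != "__config__"})
        return model


def build_detector(
    num_classes: int,
    width_multiplier: float = 1.0,
    attention: str = "cbam",
    **kwargs,
) -> YoloV3:
    """Construct a CBAM-YOLOv3 (or plain YOLOv3 with ``attention='none'``)."""
    return YoloV3(num_classes, width_multiplier, attention, **kwargs)


def decode_boxes(
    raws: Sequence[np.ndarray],
    anchors: AnchorSet,
    input_size: int,
    confidence_threshold: float = 0.0,
    class_names: Sequence[str] | None = None,
) -> list[BoundingBox]:
    """Decode one image's raw predictions into scored boxes on the input frame.

    ``raws`` holds one (3, gy, gx, 5+C) array per scale (strides 32/16/8).
    Per-class confidences are sigmoid(objectness) * sigmoid(class logit);
    boxes are clipped to the canvas and only scores above
    ``confidence_threshold`` are materialised.
    """
    out: list[BoundingBox] = []
    for scale_idx, raw in enumerate(raws):
        na, gy, gx, pa = raw.shape
        num_classes = pa - 5
        stride = input_size // gx
        pri = np.asarray(anchors.for_scale(scale_idx), dtype=np.float64)
        cx = np.arange(gx)[None, None, :]
        cy = np.arange(gy)[None, :, None]
        bx = (sigmoid(raw[..., 0]) + cx) * stride
        by = (sigmoid(raw[..., 1]) + cy) * stride
        bw = pri[:, 0][:, None, None] * np.exp(raw[..., 2])
        bh = pri[:, 1][:, None, None] * np.exp(raw[..., 3])
        obj = sigmoid(raw[..., 4])
        cls = sigmoid(raw[..., 5:])
        conf = obj[..., None] * cls
        a_idx, y_idx, x_idx, c_idx = np.nonzero(conf >= confidence_threshold)
        for a, yy, xx, cc in zip(a_idx, y_idx, x_idx, c_idx):
            w2, h2 = bw[a, yy, xx] / 2.0, bh[a, yy, xx] / 2.0
            xmin = max(bx[a, yy, xx] - w2, 0.0)
            ymin = max(by[a, yy, xx] - h2, 0.0)
            xmax = min(bx[a, yy, xx] + w2, float(input_size))
            ymax = min(by[a, yy, xx] + h2, float(input_size))
            if xmax <= xmin or ymax <= ymin:
                continue
            label = class_names[cc] if class_names else f"class{cc}"
            c = float(conf[a, yy, xx, cc])
            out.append(BoundingBox(xmin, ymin, xmax, ymax, label, min(max(c, 1e-9), 1.0)))
    return out
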