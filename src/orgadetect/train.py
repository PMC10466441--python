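"""Training: anchor estimation, the YOLOv3 composite loss, and the two-phase
Adam schedule.

The loss is the standard single-stage composite: squared error on the
t-space box offsets at positive anchors, binary cross-entropy on objectness
(with positives weighted against the overwhelming negative background) and
binary cross-entropy on class logits. Positive anchors are chosen by best
co-centered (shape) IoU between each ground-truth box and the nine priors;
at the target's cell, non-best anchors whose shape IoU still exceeds
``ignore_iou_threshold`` are excluded from the negative-objectness term —
the mechanism that limits the positive/negative imbalance.

``ignore_iou_threshold`` additionally gates a dynamic mask: any prediction
whose decoded box overlaps some ground-truth box with IoU above the
threshold is likewise dropped from the negative term, so confident
near-duplicates of a truth are not punished as background.

Optimisation follows the stated settings: Adam, learning rates 0.001 then
0.0001 across two phases, batch sizes chosen per phase from {8, 2}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .boxes import BoundingBox
from .detect import letterbox_image
from .net.layers import sigmoid
from .net.yolov3 import STRIDES, AnchorSet, YoloV3

__all__ = [
    "TrainConfig",
    "LossBreakdown",
    "estimate_anchors",
    "encode_targets",
    "compute_loss",
    "Adam",
    "fit",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rates: tuple[float, float] = (1e-3, 1e-4)
    batch_sizes: tuple[int, int] = (8, 2)
    epochs: tuple[int, int] = (30, 30)
    input_size: int = 416
    seed: int = 0
    ignore_iou_threshold: float = 0.7
    box_weight: float = 7.5
    obj_weight: float = 10.0
    noobj_weight: float = 0.5
    augment_flips: bool = False

    def __post_init__(self) -> None:
        if any(lr <= 0 for lr in self.learning_rates):
            raise ValueError("learning rates must be positive")
        if any(bs < 1 for bs in self.batch_sizes):
            raise ValueError("batch sizes must be >= 1")


@dataclass(frozen=True)
class LossBreakdown:
    box_loss: float
    objectness_loss: float
    class_loss: float

    @property
    def total(self) -> float:
        return self.box_loss + self.objectness_loss + self.class_loss


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def _shape_iou(wh: np.ndarray, priors: np.ndarray) -> np.ndarray:
    """Co-centered IoU between (n, 2) box shapes and (k, 2) priors -> (n, k)."""
    inter = np.minimum(wh[:, None, 0], priors[None, :, 0]) * np.minimum(
        wh[:, None, 1], priors[None, :, 1]
    )
    union = wh[:, 0] * wh[:, 1]
    return inter / (union[:, None] + priors[:, 0] * priors[:, 1] - inter)


def estimate_anchors(
    boxes: Sequence[BoundingBox], k: int = 9, seed: int = 0, max_iter: int = 100
) -> AnchorSet:
    """K-means over box (width, height) with 1 - IoU distance (co-centered).

    Fully deterministic (farthest-point initialisation; ``seed`` is accepted
    for interface stability but unused); anchors sorted ascending by area.
    Fewer than ``k`` distinct shapes falls back to duplicating the nearest
    existing shapes with a warning. ``k=9`` (the detector's layout) yields an
    :class:`AnchorSet`; any other ``k`` a plain tuple of (w, h) pairs.
    """
    if len(boxes) < k:
        raise ValueError(f"anchor estimation needs at least {k} boxes, got {len(boxes)}")
    wh = np.array([[b.width, b.height] for b in boxes], dtype=np.float64)
    wh = wh[np.lexsort((wh[:, 1], wh[:, 0]))]  # canonical order: permutation-invariant
    distinct = np.unique(wh, axis=0)
    if len(distinct) < k:
        warnings.warn(
            f"only {len(distinct)} distinct box shapes for k={k}; duplicating shapes"
        )
        reps = int(np.ceil(k / len(distinct)))
        centers = np.tile(distinct, (reps, 1))[:k].astype(np.float64)
    else:
        # farthest-point initialisation in 1-IoU distance: deterministic and
        # robust to well-separated size modes
        centers = distinct[:1].copy()
        while len(centers) < k:
            d = 1.0 - _shape_iou(distinct, centers).max(axis=1)
            centers = np.vstack([centers, distinct[int(np.argmax(d))]])
        for _ in range(max_iter):
            assign = np.argmax(_shape_iou(wh, centers), axis=1)
            new = centers.copy()
            for j in range(k):
                members = wh[assign == j]
                if len(members):
                    new[j] = members.mean(axis=0)
                else:  # re-seed an empty cluster at the worst-covered box
                    worst = np.argmin(_shape_iou(wh, centers).max(axis=1))
                    new[j] = wh[worst]
            if np.allclose(new, centers, atol=1e-9):
                centers = new
                break
            centers = new
    order = np.argsort(centers[:, 0] * centers[:, 1], kind="stable")
    centers = centers[order]
    shapes = tuple((float(w), float(h)) for w, h in centers)
    return AnchorSet(shapes) if k == 9 else shapes


# ---------------------------------------------------------------------------
# target encoding and loss
# ---------------------------------------------------------------------------

@dataclass
class EncodedTargets:
    """Per-scale supervision grids for one image."""

    obj: list[np.ndarray]       # (3, g, g) 1 at positives
    ignore: list[np.ndarray]    # (3, g, g) 1 where negatives are excluded
    txywh: list[np.ndarray]     # (3, g, g, 4) t-space regression targets
    cls: list[np.ndarray]       # (3, g, g) class index, -1 where none
    box_scale: list[np.ndarray]  # (3, g, g) size-balancing weight at positives
    gt_xywh: np.ndarray = None   # (n_gt, 4) center-format truths, network frame
    num_positives: int = 0


def encode_targets(
    boxes: Sequence[BoundingBox],
    anchors: AnchorSet,
    input_size: int,
    class_names: Sequence[str],
    ignore_iou_threshold: float = 0.5,
) -> EncodedTargets:
    """Assign each ground-truth box to its best-shape anchor and grid cell."""
    grids = [input_size // s for s in STRIDES]
    enc = EncodedTargets(
        obj=[np.zeros((3, g, g), dtype=np.float32) for g in grids],
        ignore=[np.zeros((3, g, g), dtype=np.float32) for g in grids],
        txywh=[np.zeros((3, g, g, 4), dtype=np.float32) for g in grids],
        cls=[np.full((3, g, g), -1, dtype=np.int64) for g in grids],
        box_scale=[np.zeros((3, g, g), dtype=np.float32) for g in grids],
        gt_xywh=np.array(
            [[*b.center, b.width, b.height] for b in boxes], dtype=np.float64
        ).reshape(-1, 4),
    )
    priors = np.asarray(anchors.anchors, dtype=np.float64)
    class_index = {c: i for i, c in enumerate(class_names)}
    for b in boxes:
        cx, cy = b.center
        w, h = b.width, b.height
        ious = _shape_iou(np.array([[w, h]]), priors)[0]
        best = int(np.argmax(ious))
        for s_idx, stride in enumerate(STRIDES):
            g = grids[s_idx]
            ci = min(int(cx / stride), g - 1)
            cj = min(int(cy / stride), g - 1)
            for a_local in range(3):
                a_global = (2 - s_idx) * 3 + a_local
                if a_global == best:
                    pw, ph = priors[a_global]
                    enc.obj[s_idx][a_local, cj, ci] = 1.0
                    enc.txywh[s_idx][a_local, cj, ci] = (
                        cx / stride - ci,
                        cy / stride - cj,
                        np.log(w / pw),
                        np.log(h / ph),
                    )
                    enc.cls[s_idx][a_local, cj, ci] = class_index[b.label]
                    enc.box_scale[s_idx][a_local, cj, ci] = 2.0 - (w * h) / input_size**2
                    enc.num_positives += 1
                elif ious[a_global] > ignore_iou_threshold:
                    enc.ignore[s_idx][a_local, cj, ci] = 1.0
    return enc


def _bce_with_logits(logit: np.ndarray, target: np.ndarray) -> np.ndarray:
    # stable: max(l, 0) - l*t + log(1 + exp(-|l|))
    return np.maximum(logit, 0.0) - logit * target + np.log1p(np.exp(-np.abs(logit)))


def _pred_iou_mask(
    raw: np.ndarray, targets: Sequence[EncodedTargets], scale_idx: int,
    anchors: AnchorSet, input_size: int, threshold: float,
) -> np.ndarray:
    """(N, 3, g, g) mask of predictions whose decoded box overlaps any truth
    with IoU above ``threshold`` (treated as constant wrt the parameters)."""
    n, _, gy, gx, _ = raw.shape
    stride = input_size // gx
    pri = np.asarray(anchors.for_scale(scale_idx), dtype=np.float64)
    bx = (sigmoid(raw[..., 0]) + np.arange(gx)[None, None, None, :]) * stride
    by = (sigmoid(raw[..., 1]) + np.arange(gy)[None, None, :, None]) * stride
    bw = pri[:, 0][None, :, None, None] * np.exp(np.minimum(raw[..., 2], 10.0))
    bh = pri[:, 1][None, :, None, None] * np.exp(np.minimum(raw[..., 3], 10.0))
    mask = np.zeros((n, 3, gy, gx), dtype=bool)
    for i, t in enumerate(targets):
        if t.gt_xywh is None or len(t.gt_xywh) == 0:
            continue
        x0, y0 = bx[i] - bw[i] / 2, by[i] - bh[i] / 2
        x1, y1 = bx[i] + bw[i] / 2, by[i] + bh[i] / 2
        best = np.zeros_like(bx[i])
        for gcx, gcy, gw, gh in t.gt_xywh:
            ix = np.minimum(x1, gcx + gw / 2) - np.maximum(x0, gcx - gw / 2)
            iy = np.minimum(y1, gcy + gh / 2) - np.maximum(y0, gcy - gh / 2)
            inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
            union = bw[i] * bh[i] + gw * gh - inter
            np.maximum(best, inter / union, out=best)
        mask[i] = best > threshold
    return mask


def compute_loss(
    raws: Sequence[np.ndarray],
    targets: Sequence[EncodedTargets],
    config: TrainConfig,
    num_classes: int,
    return_grads: bool = False,
    anchors: AnchorSet | None = None,
    input_size: int = 416,
):
    """Composite loss over a batch; optionally also its gradient wrt the raw
    predictions (for backprop). ``raws[s]`` is (N, 3, g, g, 5+C); ``targets``
    holds one :class:`EncodedTargets` per batch image.

    When ``anchors`` is given the dynamic prediction-IoU ignore mask is
    applied on top of the static (shape-IoU, at-cell) one; without anchors
    only the static mask is used.

    Returns ``LossBreakdown`` (totals averaged over the batch) and, when
    requested, per-scale gradient arrays matching ``raws``.
    """
    n = raws[0].shape[0]
    box_l = obj_l = cls_l = 0.0
    grads = [np.zeros_like(r) for r in raws] if return_grads else None
    for s in range(len(raws)):
        raw = raws[s]
        obj_t = np.stack([t.obj[s] for t in targets])
        ign = np.stack([t.ignore[s] for t in targets]) > 0.5
        txywh = np.stack([t.txywh[s] for t in targets])
        cls_t = np.stack([t.cls[s] for t in targets])
        bscale = np.stack([t.box_scale[s] for t in targets])
        if anchors is not None:
            ign |= _pred_iou_mask(
                raw, targets, s, anchors, input_size, config.ignore_iou_threshold
            )

        pos = obj_t > 0.5
        # objectness: positives weighted up, negatives (not ignored) down
        obj_logit = raw[..., 4]
        neg_mask = (~pos) & (~ign)
        w_obj = pos * config.obj_weight + neg_mask * config.noobj_weight
        obj_l += float((w_obj * _bce_with_logits(obj_logit, obj_t)).sum()) / n

        if pos.any():
            sx = sigmoid(raw[..., 0])
            sy = sigmoid(raw[..., 1])
            dx = (sx - txywh[..., 0]) * pos
            dy = (sy - txywh[..., 1]) * pos
            dw = (raw[..., 2] - txywh[..., 2]) * pos
            dh = (raw[..., 3] - txywh[..., 3]) * pos
            w_box = config.box_weight * bscale
            box_l += float((w_box * (dx**2 + dy**2 + dw**2 + dh**2)).sum()) / n

            cls_logits = raw[..., 5:]
            onehot = np.zeros_like(cls_logits)
            pidx = np.nonzero(pos)
            onehot[pidx + (cls_t[pidx],)] = 1.0
            cls_l += float(
                (_bce_with_logits(cls_logits, onehot) * pos[..., None]).sum()
            ) / n

        if return_grads:
            g = grads[s]
            g[..., 4] = w_obj * (sigmoid(obj_logit) - obj_t) / n
            if pos.any():
                g[..., 0] = w_box * 2.0 * dx * sx * (1 - sx) / n
                g[..., 1] = w_box * 2.0 * dy * sy * (1 - sy) / n
                g[..., 2] = w_box * 2.0 * dw / n
                g[..., 3] = w_box * 2.0 * dh / n
                g[..., 5:] = (sigmoid(cls_logits) - onehot) * pos[..., None] / n
    breakdown = LossBreakdown(box_l, obj_l, cls_l)
    if not np.isfinite(breakdown.total):
        raise FloatingPointError("non-finite loss")
    return (breakdown, grads) if return_grads else breakdown


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if not p.trainable:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

def _flip_boxes(boxes, size, horizontal, vertical):
    out = []
    for b in boxes:
        xmin, xmax = (size - b.xmax, size - b.xmin) if horizontal else (b.xmin, b.xmax)
        ymin, ymax = (size - b.ymax, size - b.ymin) if vertical else (b.ymin, b.ymax)
        out.append(BoundingBox(xmin, ymin, xmax, ymax, b.label, b.confidence))
    return out


def _prepare(images, annotations, class_names, anchors, config, augment=False):
    """Letterbox + encode every image; with ``augment`` also the three
    flipped variants (horizontal, vertical, both), pre-encoded so epochs pay
    no augmentation cost."""
    variants = [(False, False)] + ([(True, False), (False, True), (True, True)] if augment else [])
    xs, encs = [], []
    for img, boxes in zip(images, annotations):
        x, tf = letterbox_image(img, config.input_size)
        net_boxes = [tf.to_network(b) for b in boxes]
        per_img_x, per_img_enc = [], []
        for hflip, vflip in variants:
            xv = x
            if hflip:
                xv = xv[:, :, ::-1]
            if vflip:
                xv = xv[:, ::-1, :]
            bv = _flip_boxes(net_boxes, config.input_size, hflip, vflip)
            per_img_x.append(np.ascontiguousarray(xv))
            per_img_enc.append(
                encode_targets(bv, anchors, config.input_size, class_names,
                               config.ignore_iou_threshold)
            )
        xs.append(per_img_x)
        encs.append(per_img_enc)
    return xs, encs


def fit(
    model: YoloV3,
    train_images: Sequence[np.ndarray],
    train_boxes: Sequence[Sequence[BoundingBox]],
    test_images: Sequence[np.ndarray] = (),
    test_boxes: Sequence[Sequence[BoundingBox]] = (),
    config: TrainConfig = TrainConfig(),
    class_names: Sequence[str] | None = None,
    log_path: str | Path | None = None,
) -> list[dict]:
    """Two-phase training loop; returns the per-epoch loss history.

    Anchors are re-estimated from the training boxes (letterboxed to the
    network frame) before optimisation. The model snapshot with the best
    held-out total loss is restored at the end; on divergence the last
    finite state is kept and a warning is raised.
    """
    if len(train_images) == 0:
        raise ValueError("training set is empty")
    if class_names is None:
        class_names = ["organoid"] if model.num_classes == 1 else ["active", "aging"]
    all_net_boxes = []
    for img, boxes in zip(train_images, train_boxes):
        _, tf = letterbox_image(img, config.input_size)
        all_net_boxes.extend(tf.to_network(b) for b in boxes)
    if len(all_net_boxes) >= 9:
        model.anchors = estimate_anchors(all_net_boxes, k=9, seed=config.seed)

    x_train, enc_train = _prepare(
        train_images, train_boxes, class_names, model.anchors, config,
        augment=config.augment_flips,
    )
    n_variants = len(x_train[0])
    if len(test_images):
        xt, et = _prepare(test_images, test_boxes, class_names, model.anchors, config)
        x_test = np.stack([v[0] for v in xt])
        enc_test = [v[0] for v in et]
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rates[0])
    history: list[dict] = []
    best = (np.inf, None)
    n = len(train_images)

    for phase in (0, 1):
        optimizer.lr = config.learning_rates[phase]
        bs = config.batch_sizes[phase]
        for epoch in range(config.epochs[phase]):
            order = rng.permutation(n)
            sums = np.zeros(3)
            nb = 0
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                var = rng.integers(0, n_variants, size=len(idx))
                xb = np.stack([x_train[i][v] for i, v in zip(idx, var)])
                encb = [enc_train[i][v] for i, v in zip(idx, var)]
                raws = model.forward(xb, train=True)
                try:
                    breakdown, grads = compute_loss(
                        raws, encb, config, model.num_classes, return_grads=True,
                        anchors=model.anchors, input_size=config.input_size,
                    )
                except FloatingPointError:
                    warnings.warn("training diverged; keeping last finite checkpoint")
                    if best[1] is not None:
                        model.load_arrays(best[1])
                    return history
                model.zero_grad()
                model.backward(grads)
                optimizer.step()
                sums += (breakdown.box_loss, breakdown.objectness_loss, breakdown.class_loss)
                nb += 1
            row = {
                "epoch": len(history),
                "phase": phase,
                "box_loss": sums[0] / nb,
                "objectness_loss": sums[1] / nb,
                "class_loss": sums[2] / nb,
                "total": sums.sum() / nb,
                "split": "train",
            }
            if len(test_images):
                t_raws = model.forward(x_test, train=False)
                t_loss = compute_loss(t_raws, enc_test, config, model.num_classes,
                                      anchors=model.anchors, input_size=config.input_size)
                row["test_total"] = t_loss.total
                if t_loss.total < best[0]:
                    best = (t_loss.total, {k: v.copy() for k, v in model.state_arrays().items()})
            history.append(row)
    if best[1] is not None:
        model.load_arrays(best[1])
    if log_path is not None:
        import csv as _csv

        keys = sorted({k for r in history for k in r})
        with open(log_path, "w", newline="") as fh:
            wr = _csv.DictWriter(fh, fieldnames=keys)
            wr.writeheader()
            wr.writerows(history)
    return history
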