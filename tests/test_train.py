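"""Anchor clustering, the composite detection loss (against a loop-based
reference), analytic gradients (against finite differences), and the
optimisation loop's basic contracts."""

import numpy as np
import pytest

from orgadetect.boxes import BoundingBox
from orgadetect.net.yolov3 import STRIDES, AnchorSet, DEFAULT_ANCHORS, YoloV3
from orgadetect.train import (
    Adam,
    TrainConfig,
    compute_loss,
    encode_targets,
    estimate_anchors,
    fit,
)


def make_boxes(rng, n, canvas=416, sizes=(20, 120), label="active"):
    out = []
    for _ in range(n):
        w, h = rng.uniform(*sizes, size=2)
        x0 = rng.uniform(0, canvas - w)
        y0 = rng.uniform(0, canvas - h)
        out.append(BoundingBox(x0, y0, x0 + w, y0 + h, label))
    return out


class TestEstimateAnchors:
    def test_degenerate_identical_boxes(self):
        boxes = [BoundingBox(0, 0, 60, 60)] * 20
        with pytest.warns(UserWarning):
            a = estimate_anchors(boxes, seed=0)
        assert all(wh == (60.0, 60.0) for wh in a.anchors)

    def test_sorted_and_deterministic(self, rng):
        boxes = make_boxes(rng, 200)
        a = estimate_anchors(boxes, seed=3)
        b = estimate_anchors(boxes, seed=3)
        assert a == b
        areas = [w * h for w, h in a.anchors]
        assert areas == sorted(areas)

    def test_permutation_invariant(self, rng):
        boxes = make_boxes(rng, 100)
        a = estimate_anchors(boxes, seed=5)
        b = estimate_anchors(list(reversed(boxes)), seed=5)
        assert a == b

    def test_too_few_boxes_rejected(self):
        with pytest.raises(ValueError):
            estimate_anchors([BoundingBox(0, 0, 10, 10)] * 5, k=9)


class TestEstimateAnchorsModes:
    def test_well_separated_sizes_within_one_pixel(self, rng):
        """K-means with shape-IoU distance recovers well-separated size modes."""
        modes = [(20.0, 20.0), (60.0, 60.0), (150.0, 150.0)]
        boxes = []
        for w, h in modes:
            for _ in range(40):
                dw, dh = rng.uniform(-0.4, 0.4, size=2)
                boxes.append(BoundingBox(0, 0, w + dw, h + dh))
        # exhaustive-assignment oracle: every box belongs to its nearest mode,
        # so each cluster mean must equal the per-mode sample mean
        got = sorted(estimate_anchors(boxes, k=3, seed=2), key=lambda t: t[0] * t[1])
        for (gw, gh), (mw, mh) in zip(got, modes):
            assert abs(gw - mw) < 1 and abs(gh - mh) < 1


def loss_oracle(raws, targets, config, anchors, input_size):
    """Cell-by-cell recomputation of the composite loss."""

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    def bce(logit, t):
        p = sig(logit)
        return -(t * np.log(p + 1e-300) + (1 - t) * np.log(1 - p + 1e-300))

    n = raws[0].shape[0]
    box_l = obj_l = cls_l = 0.0
    for s, raw in enumerate(raws):
        _, na, gy, gx, pa = raw.shape
        stride = input_size // gx
        pri = anchors.for_scale(s)
        for i in range(n):
            t = targets[i]
            for a in range(na):
                for yy in range(gy):
                    for xx in range(gx):
                        v = raw[i, a, yy, xx]
                        is_pos = t.obj[s][a, yy, xx] > 0.5
                        ignored = t.ignore[s][a, yy, xx] > 0.5
                        if not is_pos and not ignored and len(t.gt_xywh):
                            bx = (sig(v[0]) + xx) * stride
                            by = (sig(v[1]) + yy) * stride
                            bw = pri[a][0] * np.exp(min(v[2], 10.0))
                            bh = pri[a][1] * np.exp(min(v[3], 10.0))
                            for gcx, gcy, gw, gh in t.gt_xywh:
                                ix = min(bx + bw / 2, gcx + gw / 2) - max(bx - bw / 2, gcx - gw / 2)
                                iy = min(by + bh / 2, gcy + gh / 2) - max(by - bh / 2, gcy - gh / 2)
                                inter = max(ix, 0) * max(iy, 0)
                                if inter / (bw * bh + gw * gh - inter) > config.ignore_iou_threshold:
                                    ignored = True
                                    break
                        if is_pos:
                            obj_l += config.obj_weight * bce(v[4], 1.0)
                            tx, ty, tw, th = t.txywh[s][a, yy, xx]
                            wb = config.box_weight * t.box_scale[s][a, yy, xx]
                            box_l += wb * (
                                (sig(v[0]) - tx) ** 2 + (sig(v[1]) - ty) ** 2
                                + (v[2] - tw) ** 2 + (v[3] - th) ** 2
                            )
                            for c in range(pa - 5):
                                cls_l += bce(v[5 + c], 1.0 if c == t.cls[s][a, yy, xx] else 0.0)
                        elif not ignored:
                            obj_l += config.noobj_weight * bce(v[4], 0.0)
    return box_l / n, obj_l / n, cls_l / n


class TestComputeLoss:
    def encode(self, boxes, anchors, nc=2, size=416):
        names = ["active", "aging"][:nc]
        return encode_targets(boxes, anchors, size, names)

    def test_perfect_prediction_near_zero_box_and_objectness(self):
        anchors = AnchorSet(DEFAULT_ANCHORS)
        boxes = [BoundingBox(100, 100, 180, 170, "active")]
        enc = self.encode(boxes, anchors)
        raws = [np.full((1, 3, g, g, 7), 0.0) for g in (13, 26, 52)]
        for r in raws:
            r[..., 4] = -40.0
        for s in range(3):
            pos = np.nonzero(enc.obj[s] > 0.5)
            for a, yy, xx in zip(*pos):
                tx, ty, tw, th = enc.txywh[s][a, yy, xx]
                logit = lambda p: np.log(p / (1 - p))
                raws[s][0, a, yy, xx, :5] = [logit(tx), logit(ty), tw, th, 40.0]
                raws[s][0, a, yy, xx, 5 + enc.cls[s][a, yy, xx]] = 40.0
                raws[s][0, a, yy, xx, 5 + 1 - enc.cls[s][a, yy, xx]] = -40.0
        bl = compute_loss(raws, [enc], TrainConfig(), 2, anchors=anchors)
        assert bl.box_loss == pytest.approx(0.0, abs=1e-6)
        assert bl.objectness_loss == pytest.approx(0.0, abs=1e-6)
        assert bl.class_loss == pytest.approx(0.0, abs=1e-6)

    def test_empty_targets_background_only(self):
        anchors = AnchorSet(DEFAULT_ANCHORS)
        enc = self.encode([], anchors)
        raws = [np.full((1, 3, g, g, 7), 0.0) for g in (13, 26, 52)]
        for r in raws:
            r[..., 4] = -40.0  # confident background everywhere
        bl = compute_loss(raws, [enc], TrainConfig(), 2, anchors=anchors)
        assert bl.box_loss == 0.0 and bl.class_loss == 0.0
        assert bl.total == pytest.approx(0.0, abs=1e-6)

    def test_total_is_sum_of_components(self, rng):
        anchors = AnchorSet(DEFAULT_ANCHORS)
        enc = self.encode(make_boxes(rng, 3), anchors)
        raws = [rng.standard_normal((1, 3, g, g, 7)) for g in (13, 26, 52)]
        bl = compute_loss(raws, [enc], TrainConfig(), 2, anchors=anchors)
        assert bl.total == pytest.approx(bl.box_loss + bl.objectness_loss + bl.class_loss, rel=1e-9)

    def test_matches_loop_oracle(self, rng):
        anchors = AnchorSet(DEFAULT_ANCHORS)
        cfg = TrainConfig()
        boxes = [
            BoundingBox(50, 60, 150, 160, "active"),
            BoundingBox(250, 240, 380, 390, "aging"),
        ]
        enc = [self.encode(boxes, anchors), self.encode([], anchors)]
        raws = [rng.standard_normal((2, 3, g, g, 7)) for g in (13, 26, 52)]
        bl = compute_loss(raws, enc, cfg, 2, anchors=anchors)
        ob, oo, oc = loss_oracle(raws, enc, cfg, anchors, 416)
        assert bl.box_loss == pytest.approx(ob, rel=1e-5)
        assert bl.objectness_loss == pytest.approx(oo, rel=1e-5)
        assert bl.class_loss == pytest.approx(oc, rel=1e-5)

    def test_gradients_match_finite_differences(self):
        # float64 end-to-end audit on a miniature network
        m = YoloV3(2, width_multiplier=0.125, stage_blocks=(1, 1, 1, 1, 1),
                   input_size=64, seed=3)
        m.set_dtype(np.float64)
        rng = np.random.default_rng(1)
        x = rng.random((2, 3, 64, 64))
        boxes = [BoundingBox(10, 12, 40, 44, "active"), BoundingBox(30, 5, 60, 30, "aging")]
        enc = [encode_targets(boxes, m.anchors, 64, ["active", "aging"])] * 2
        cfg = TrainConfig()

        def total():
            return compute_loss(m.forward(x, train=True), enc, cfg, 2,
                                anchors=m.anchors, input_size=64).total

        raws = m.forward(x, train=True)
        _, grads = compute_loss(raws, enc, cfg, 2, return_grads=True,
                                anchors=m.anchors, input_size=64)
        m.zero_grad()
        m.backward(grads)
        params = m.parameters()
        check_rng = np.random.default_rng(7)
        for pi in check_rng.choice(len(params), size=8, replace=False):
            p = params[pi]
            flat = p.data.reshape(-1)
            idx = int(check_rng.integers(flat.size))
            eps = 1e-6
            orig = flat[idx].item()
            flat[idx] = orig + eps
            lp = total()
            flat[idx] = orig - eps
            lm = total()
            flat[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = p.grad.reshape(-1)[idx]
            assert num == pytest.approx(ana, abs=max(1e-5, 1e-3 * abs(num))), p.name


class TestFit:
    def tiny_fixture(self, rng, n=4, size=128):
        from orgadetect.synthgen import SceneConfig, render_scene, sample_scene

        cfg = SceneConfig(width_px=size, height_px=size, count_range=(2, 3),
                          diameter_range_px=(24, 48), diameter_log_mean=3.5,
                          contrast_range=(0.9, 1.0))
        imgs, boxes = [], []
        for i in range(n):
            spec = sample_scene(cfg, seed=int(rng.integers(2**31)))
            im, bx = render_scene(spec, labels="organoid")
            imgs.append(im)
            boxes.append(bx)
        return imgs, boxes

    def make_model(self):
        return YoloV3(1, width_multiplier=0.125, stage_blocks=(1, 1, 1, 1, 1),
                      input_size=128, seed=2)

    def test_loss_decreases_and_history_logged(self, rng, tmp_path):
        imgs, boxes = self.tiny_fixture(rng)
        cfg = TrainConfig(epochs=(12, 3), input_size=128, seed=0)
        model = self.make_model()
        hist = fit(model, imgs, boxes, config=cfg, log_path=tmp_path / "log.csv")
        assert hist[-1]["total"] < hist[0]["total"]
        assert (tmp_path / "log.csv").exists()
        assert all(h["total"] >= 0 for h in hist)

    def test_first_epoch_deterministic_under_seed(self, rng):
        imgs, boxes = self.tiny_fixture(rng)
        cfg = TrainConfig(epochs=(1, 0), input_size=128, seed=9)
        h1 = fit(self.make_model(), imgs, boxes, config=cfg)
        h2 = fit(self.make_model(), imgs, boxes, config=cfg)
        assert h1[0]["total"] == h2[0]["total"]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            fit(self.make_model(), [], [], config=TrainConfig())
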