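"""Attention blocks, detector construction, and box decoding, each checked
against plain loop-based recomputations."""

import numpy as np
import pytest

from orgadetect.boxes import BoundingBox
from orgadetect.net.cbam import CBAM, ChannelAttention, SpatialAttention
from orgadetect.net.layers import sigmoid
from orgadetect.net.yolov3 import AnchorSet, DEFAULT_ANCHORS, YoloV3, build_detector, decode_boxes


def channel_weights_oracle(layer, x):
    """Loop-based channel attention: shared MLP on avg- and max-pooled
    descriptors, logistic of the sum."""
    n, c, h, w = x.shape
    out = np.zeros((n, c))
    for i in range(n):
        avg = np.array([x[i, ch].mean() for ch in range(c)])
        mx = np.array([x[i, ch].max() for ch in range(c)])
        logits = np.zeros(c)
        for d in (avg, mx):
            hid = np.maximum(layer.w1.data @ d + layer.b1.data, 0.0)
            logits += layer.w2.data @ hid + layer.b2.data
        out[i] = 1.0 / (1.0 + np.exp(-logits))
    return out


def spatial_weights_oracle(layer, x):
    """Loop-based spatial attention: 7x7 conv over stacked mean/max maps."""
    n, c, h, w = x.shape
    k = layer.conv.k
    half = k // 2
    kernel = layer.conv.w.data  # (1, 2, k, k)
    bias = layer.conv.b.data[0]
    out = np.zeros((n, h, w))
    mean_map = x.mean(axis=1)
    max_map = x.max(axis=1)
    for i in range(n):
        stacked = np.stack([mean_map[i], max_map[i]])
        padded = np.zeros((2, h + 2 * half, w + 2 * half))
        padded[:, half : half + h, half : half + w] = stacked
        for y in range(h):
            for xx in range(w):
                acc = bias
                for ch in range(2):
                    acc += float(
                        (padded[ch, y : y + k, xx : xx + k] * kernel[0, ch]).sum()
                    )
                out[i, y, xx] = 1.0 / (1.0 + np.exp(-acc))
    return out


class TestChannelAttention:
    def test_zero_mlp_gives_half_weights(self, rng):
        layer = ChannelAttention(8, 4)
        for p in layer.params():
            p.data[...] = 0.0
        x = rng.standard_normal((2, 8, 5, 5)).astype(np.float32)
        assert np.allclose(layer.weights(x), 0.5)

    def test_constant_input_doubles_mlp_logit(self, rng):
        layer = ChannelAttention(8, 4, rng=rng)
        x = np.full((1, 8, 4, 4), 3.25, dtype=np.float32)
        d = x[0].reshape(8, -1).mean(axis=1)
        hid = np.maximum(layer.w1.data @ d + layer.b1.data, 0.0)
        expect = sigmoid(2.0 * (layer.w2.data @ hid + layer.b2.data))
        assert np.allclose(layer.weights(x)[0], expect, atol=1e-6)

    def test_matches_loop_oracle(self, rng):
        layer = ChannelAttention(8, 4, rng=rng)
        x = rng.standard_normal((3, 8, 4, 4))
        w = layer.weights(x)
        assert np.allclose(w, channel_weights_oracle(layer, x), atol=1e-6)
        assert ((0 < w) & (w < 1)).all()
        y = layer.forward(x.copy(), train=True)
        assert np.allclose(y, x * w[:, :, None, None], atol=1e-6)


class TestSpatialAttention:
    def test_zero_conv_gives_uniform_half(self, rng):
        layer = SpatialAttention(7)
        for p in layer.params():
            p.data[...] = 0.0
        x = rng.standard_normal((2, 6, 9, 9)).astype(np.float32)
        assert np.allclose(layer.weights(x), 0.5)

    def test_constant_input_constant_interior_weights(self, rng):
        # away from the zero-padded border the conv response is translation
        # invariant, so a constant map gives constant weights there
        layer = SpatialAttention(7, rng=rng)
        x = np.full((1, 4, 20, 20), 1.5, dtype=np.float32)
        w = layer.weights(x)[0]
        interior = w[3:-3, 3:-3]
        assert np.allclose(interior, interior[0, 0], atol=1e-6)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            SpatialAttention(6)

    def test_matches_loop_oracle(self, rng):
        layer = SpatialAttention(7, rng=rng)
        x = rng.standard_normal((2, 6, 8, 8))
        w = layer.weights(x)
        assert np.allclose(w, spatial_weights_oracle(layer, x), atol=1e-6)
        y = layer.forward(x.copy(), train=True)
        assert np.allclose(y, x * w[:, None], atol=1e-6)


TINY = dict(width_multiplier=0.125, stage_blocks=(1, 1, 1, 1, 1), input_size=96)


class TestBuildDetector:
    @pytest.mark.parametrize("nc, per_anchor", [(1, 6), (2, 7)])
    def test_per_anchor_channels(self, nc, per_anchor):
        m = YoloV3(nc, **TINY, seed=0)
        raws = m.forward(np.zeros((1, 3, 96, 96), dtype=np.float32), train=False)
        assert [r.shape for r in raws] == [
            (1, 3, 3, 3, per_anchor),
            (1, 3, 6, 6, per_anchor),
            (1, 3, 12, 12, per_anchor),
        ]

    def test_attention_adds_only_attention_parameters(self):
        plain = YoloV3(1, **TINY, attention="none", seed=0)
        cbam = YoloV3(1, **TINY, attention="cbam", seed=0)
        plain_names = {p.name: p.data.shape for p in plain.parameters()}
        cbam_names = {p.name: p.data.shape for p in cbam.parameters()}
        extra = set(cbam_names) - set(plain_names)
        assert set(plain_names) <= set(cbam_names)
        assert extra and all(".cbam." in n for n in extra)
        for n in plain_names:
            assert plain_names[n] == cbam_names[n]

    def test_bypassed_attention_reproduces_plain_network(self, rng):
        plain = YoloV3(1, **TINY, attention="none", seed=4)
        cbam = YoloV3(1, **TINY, attention="cbam", seed=4)
        by_name = {p.name: p for p in plain.parameters()}
        for p in cbam.parameters():
            if p.name in by_name:
                p.data[...] = by_name[p.name].data
        for blk in cbam.attention_blocks():
            blk.bypass = True
        x = rng.random((2, 3, 96, 96)).astype(np.float32)
        for a, b in zip(plain.forward(x, train=False), cbam.forward(x, train=False)):
            assert np.array_equal(a, b)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            YoloV3(0)
        with pytest.raises(ValueError):
            YoloV3(1, width_multiplier=0.0)
        with pytest.raises(ValueError):
            YoloV3(1, input_size=100)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        m = YoloV3(2, **TINY, seed=1)
        x = rng.random((1, 3, 96, 96)).astype(np.float32)
        m.forward(x, train=True)  # populate batchnorm running stats
        before = m.forward(x, train=False)
        m.save(tmp_path / "ckpt.npz")
        again = YoloV3.load(tmp_path / "ckpt.npz")
        after = again.forward(x, train=False)
        for a, b in zip(before, after):
            assert np.array_equal(a, b)
        assert again.num_classes == 2 and again.attention == "cbam"


def decode_oracle(raws, anchors, input_size):
    """Cell-by-cell loop decode of the YOLOv3 box parameterisation."""
    out = []
    for s, raw in enumerate(raws):
        na, gy, gx, pa = raw.shape
        stride = input_size // gx
        pri = anchors.for_scale(s)
        for a in range(na):
            for yy in range(gy):
                for xx in range(gx):
                    t = raw[a, yy, xx]
                    bx = (1 / (1 + np.exp(-t[0])) + xx) * stride
                    by = (1 / (1 + np.exp(-t[1])) + yy) * stride
                    bw = pri[a][0] * np.exp(t[2])
                    bh = pri[a][1] * np.exp(t[3])
                    obj = 1 / (1 + np.exp(-t[4]))
                    for c in range(pa - 5):
                        conf = obj / (1 + np.exp(-t[5 + c]))
                        out.append((bx, by, bw, bh, c, conf))
    return out


class TestDecodeBoxes:
    def grid_raws(self, rng, pa=6):
        return [rng.standard_normal((3, g, g, pa)) for g in (2, 4, 8)]

    def test_zero_offsets_center_of_cell(self):
        raws = [np.zeros((3, g, g, 6)) for g in (2, 4, 8)]
        for r in raws:
            r[..., 4] = 10.0
            r[..., 5] = 10.0
        small = AnchorSet(tuple((4 + 0.1 * i, 4 + 0.1 * i) for i in range(9)))
        boxes = decode_boxes(raws, small, 64, confidence_threshold=0.9)
        b = boxes[0]  # first: scale stride 32, cell (0,0)
        cx, cy = b.center
        assert (cx, cy) == pytest.approx((0.5 * 32, 0.5 * 32))

    def test_zero_size_offsets_give_anchor_size(self):
        raws = [np.zeros((3, g, g, 6)) for g in (2, 4, 8)]
        for r in raws:
            r[..., 4] = r[..., 5] = 10.0
        anchors = AnchorSet(tuple((10 + i, 12 + i) for i in range(9)))
        boxes = decode_boxes(raws, anchors, 256, confidence_threshold=0.9)
        interior = [b for b in boxes if 40 < b.center[0] < 200 and 40 < b.center[1] < 200]
        sizes = {(round(b.width, 6), round(b.height, 6)) for b in interior}
        assert sizes <= {(10.0 + i, 12.0 + i) for i in range(9)}

    def test_width_monotone_in_tw(self):
        small = AnchorSet(tuple((4 + 0.1 * i, 4 + 0.1 * i) for i in range(9)))
        widths = []
        for tw in (-1.0, -0.5, 0.0, 0.5, 1.0):
            raws = [np.full((3, g, g, 6), -20.0) for g in (2, 4, 8)]
            raws[0][0, 1, 1, :] = [0, 0, tw, 0, 10, 10]
            (b,) = decode_boxes(raws, small, 64, confidence_threshold=0.5)
            widths.append(b.width)
        assert all(a < b for a, b in zip(widths, widths[1:]))

    def test_matches_loop_oracle(self, rng):
        anchors = AnchorSet(DEFAULT_ANCHORS)
        raws = self.grid_raws(rng)
        got = decode_boxes(raws, anchors, 64, confidence_threshold=0.0)
        expected = decode_oracle(raws, anchors, 64)
        assert len(got) == len(expected)
        for b, (bx, by, bw, bh, c, conf) in zip(got, expected):
            # compare in center form before canvas clipping
            assert b.confidence == pytest.approx(min(max(conf, 1e-9), 1.0), abs=1e-5)
            assert b.xmin == pytest.approx(max(bx - bw / 2, 0.0), abs=1e-5)
            assert b.ymax == pytest.approx(min(by + bh / 2, 64.0), abs=1e-5)

    def test_confidences_in_unit_interval(self, rng):
        boxes = decode_boxes(self.grid_raws(rng), AnchorSet(DEFAULT_ANCHORS), 64)
        assert all(0 < b.confidence <= 1 for b in boxes)


class TestAnchorSet:
    def test_unsorted_rejected(self):
        bad = tuple(reversed(DEFAULT_ANCHORS))
        with pytest.raises(ValueError):
            AnchorSet(bad)

    def test_scale_assignment_covers_all_nine(self):
        a = AnchorSet(DEFAULT_ANCHORS)
        seen = [p for s in range(3) for p in a.for_scale(s)]
        assert sorted(seen) == sorted(DEFAULT_ANCHORS)
        assert a.for_scale(0) == DEFAULT_ANCHORS[6:9]  # coarsest grid, largest
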