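import numpy as np
import pytest

from orgadetect.boxes import BoundingBox


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_boxes(rng, n, canvas=200.0, labels=("organoid",), with_conf=True):
    """Random valid boxes for oracle-equivalence trials."""
    out = []
    for _ in range(n):
        x0, y0 = rng.uniform(0, canvas - 20, size=2)
        w, h = rng.uniform(5, 80, size=2)
        out.append(
            BoundingBox(
                x0,
                y0,
                min(x0 + w, canvas),
                min(y0 + h, canvas),
                label=str(rng.choice(list(labels))),
                confidence=float(rng.uniform(0.05, 1.0)) if with_conf else None,
            )
        )
    return out
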