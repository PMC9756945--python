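import numpy as np
import pytest

from cnvconfirm.depthio import RAW, NORMALIZED, CaptureTarget, DepthMatrix


def make_targets(n, chrom="chr1", start=1_000_000, length=200, gap=2000, gc=None):
    """Evenly spaced targets on one chromosome with optional GC values."""
    targets = []
    pos = start
    for i in range(n):
        g = gc[i] if gc is not None else 0.45
        targets.append(CaptureTarget(chrom, pos, pos + length, g))
        pos += length + gap
    return targets


@pytest.fixture
def small_normalized_matrix():
    """5 samples x 30 targets, baseline ~1 with mild noise; sample s0 carries
    a 0.5x deletion signal on targets 10-14."""
    rng = np.random.default_rng(42)
    targets = make_targets(30)
    values = 1.0 + 0.05 * rng.standard_normal((5, 30))
    values[0, 10:15] *= 0.5
    return DepthMatrix([f"s{i}" for i in range(5)], targets, np.abs(values), state=NORMALIZED)


@pytest.fixture
def raw_matrix():
    rng = np.random.default_rng(7)
    gc = rng.uniform(0.25, 0.75, size=50)
    targets = make_targets(50, gc=list(gc))
    values = rng.gamma(20.0, 5.0, size=(5, 50))
    return DepthMatrix([f"s{i}" for i in range(5)], targets, values, state=RAW)
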