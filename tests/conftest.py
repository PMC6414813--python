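import numpy as np
import pytest

from corticalmask.pyramid import BandInfo, SteerablePyramid, SubbandIndex


def make_toy_index(n_bands=2, side=2, extent=1.0, f0=16.0):
    """Small hand-built subband index on nested dyadic grids."""
    table, bid, pos, freq, ori = [], [], [], [], []
    offset = 0
    for b in range(n_bands):
        M = side
        n = M * M
        f = f0 / 2**b
        phi = 45.0 * (b % 4)
        table.append(BandInfo(b, "oriented", b + 1, phi, f, M, n, offset))
        coords = np.arange(M) * (extent / M) - extent / 2.0
        xx, yy = np.meshgrid(coords, coords)
        pos.append(np.column_stack([xx.ravel(), yy.ravel()]))
        bid.append(np.full(n, b))
        freq.append(np.full(n, f))
        ori.append(np.full(n, phi))
        offset += n
    return SubbandIndex(
        tuple(table),
        np.concatenate(bid),
        np.vstack(pos),
        np.concatenate(freq),
        np.concatenate(ori),
        extent,
    )


@pytest.fixture(scope="session")
def pyr16():
    """Small real pyramid (16 px, 2 scales) for cheap end-to-end checks."""
    return SteerablePyramid(16, n_scales=2, n_orients=4, samples_per_degree=16.0)


@pytest.fixture(scope="session")
def pyr64():
    """Default-geometry pyramid (64 px, 3 scales, 64 samples/deg)."""
    return SteerablePyramid(64, n_scales=3, n_orients=4, samples_per_degree=64.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def naive_normalized_response(y, b, H, gamma, K=None):
    """Per-coefficient loop implementation of divisive normalization.

    Independent oracle for the vectorized Model A/B responses.
    """
    n = len(y)
    e = [abs(y[i]) ** gamma for i in range(n)]
    x = np.zeros(n)
    for i in range(n):
        pool = b[i]
        for j in range(n):
            pool += H[i][j] * e[j]
        x[i] = np.sign(y[i]) * e[i] / pool
        if K is not None:
            x[i] *= K[i]
    return x
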