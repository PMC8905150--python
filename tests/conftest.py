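import numpy as np
import pytest

from antsync import ModelParams, fixed, exponential


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A cheap colony configuration for fast structural tests."""
    return ModelParams(
        refractory_spec=fixed(600),
        spontaneous_spec=exponential(2000),
        active_duration=100,
        n_ants=12,
        n_steps=5_001,
        seed=7,
    )


def brute_force_prominent_peaks(x, min_prominence):
    """O(n^2) topographic-prominence oracle for peak detection.

    A local maximum's prominence is its height minus the higher of the two
    deepest valleys separating it from higher terrain (or the series edge).
    Flat-topped maxima report the centre of the plateau.  Kept deliberately
    naive and independent of scipy.
    """
    x = np.asarray(x, float)
    n = x.size
    peaks = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:  # plateau [i, j] is a local max
                peaks.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    out = []
    for p in peaks:
        h = x[p]
        left = x[:p][::-1]
        higher = np.nonzero(left > h)[0]
        lmin = left[: higher[0]].min() if higher.size else left.min()
        right = x[p + 1:]
        higher = np.nonzero(right > h)[0]
        rmin = right[: higher[0]].min() if higher.size else right.min()
        if h - max(lmin, rmin) >= min_prominence:
            out.append(p)
    return np.array(out, dtype=int)
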