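import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept deliberately naive)
# ---------------------------------------------------------------------------


def naive_box_count(mask: np.ndarray, size: int) -> int:
    """Double-loop grid scan: count cells containing any foreground pixel."""
    h, w = mask.shape
    n = 0
    for i in range(0, h, size):
        for j in range(0, w, size):
            if mask[i : i + size, j : j + size].any():
                n += 1
    return n


def naive_otsu(values: np.ndarray) -> int:
    """Exhaustive between-class-variance search over all 256 split points."""
    values = np.asarray(values).ravel()
    best_t, best_v = None, -1.0
    for t in range(256):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size == 0 or hi.size == 0:
            continue
        v = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-9:
            best_v, best_t = v, t
    return best_t


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def random_masks(rng):
    """Random sparse-to-dense 64x64 binary patterns, none empty."""

    def make(n, size=64):
        out = []
        for _ in range(n):
            p = rng.uniform(0.02, 0.5)
            m = rng.random((size, size)) < p
            if not m.any():
                m[rng.integers(size), rng.integers(size)] = True
            out.append(m)
        return out

    return make
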