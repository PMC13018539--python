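import numpy as np
import pytest

from sijkit.contour import Polyline


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_open_polyline(
    rng: np.random.Generator,
    size: int = 64,
    n_range: tuple = (4, 16),
    min_spacing: float = 2.0,
) -> Polyline:
    """A roughly vertical random open contour with bounded wobble and a
    minimum vertex spacing — the shared generator for walker oracles."""
    n = int(rng.integers(*n_range))
    margin = 0.12 * size
    y = np.linspace(margin, size - 1 - margin, n) + rng.normal(0, 1.0, n)
    y = np.clip(np.sort(y), 0, size - 1)
    x = 0.5 * size + np.cumsum(rng.normal(0, 2.0, n))
    x = np.clip(x - (x.mean() - 0.5 * size), 0.1 * size, 0.9 * size)
    v = np.stack([x, y], axis=1)
    keep = [v[0]]
    for p in v[1:]:
        if np.linalg.norm(p - keep[-1]) >= min_spacing:
            keep.append(p)
    if len(keep) < 2:
        keep = [v[0], v[-1]]
    return Polyline(np.array(keep))
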