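import numpy as np
import pytest

from gutspat.geometry import PointPattern, Window
from gutspat.synth import DEFAULT_PIXEL_SIZE_UM


@pytest.fixture
def unit_window() -> Window:
    return Window.square(100.0)


@pytest.fixture
def pixel_size() -> float:
    return DEFAULT_PIXEL_SIZE_UM


def separated_pattern(
    window: Window, n: int, min_sep: float, rng: np.random.Generator, margin: float = 2.0
) -> PointPattern:
    """Uniform points with a minimum pairwise separation (for round trips)."""
    pts: list[np.ndarray] = []
    while len(pts) < n:
        cand = np.array(
            [
                rng.uniform(window.xmin + margin, window.xmax - margin),
                rng.uniform(window.ymin + margin, window.ymax - margin),
            ]
        )
        if all(np.hypot(*(cand - p)) >= min_sep for p in pts):
            pts.append(cand)
    return PointPattern(window, np.array(pts))
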