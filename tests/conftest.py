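import numpy as np
import pytest

from npcscreen.io_plate import Channel, ImageField
from npcscreen.features import FeatureConfig
from npcscreen.segmentation import ScreenConfig
from npcscreen.synthetic_plate import PhenotypeParams, render_field


@pytest.fixture(scope="session")
def screen_cfg():
    return ScreenConfig()


@pytest.fixture(scope="session")
def feat_cfg():
    return FeatureConfig()


@pytest.fixture(scope="session")
def punctate_field():
    """One rendered saturating-dose field pair (theta 0.85), reused across
    tests that only need a realistic positive-phenotype image."""
    return render_field(PhenotypeParams(theta=0.85), 512, 512, seed=42)


@pytest.fixture(scope="session")
def reticular_field():
    """One rendered vehicle field pair (theta 0.15)."""
    return render_field(PhenotypeParams(theta=0.15), 512, 512, seed=42)


def flood_fill_label(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Brute-force connected-component labeling by BFS flood fill.

    Independent oracle for the library-based labeling; O(n) but pure
    Python, so only used on small grids.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    current = 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and labels[r, c] == 0:
                current += 1
                stack = [(r, c)]
                labels[r, c] = current
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1]
                                and mask[nr, nc] and labels[nr, nc] == 0):
                            labels[nr, nc] = current
                            stack.append((nr, nc))
    return labels


def as_field(pixels, channel=Channel.GFP):
    return ImageField(np.asarray(pixels, dtype=float), channel)
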