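import numpy as np
import pytest

from otoradiomics.preprocess import DiscretizedROI
from otoradiomics.synthetic import (
    DEFAULT_CENTERS,
    ClassEffect,
    PhantomParams,
    generate_phantom,
)


def make_disc(labels: np.ndarray, n_levels: int | None = None) -> DiscretizedROI:
    """Wrap an integer label grid as a DiscretizedROI for texture tests."""
    labels = np.asarray(labels, dtype=np.int64)
    ng = int(labels.max()) if n_levels is None else n_levels
    return DiscretizedROI(labels=labels, n_levels=max(ng, 1), bin_width=1.0, roi_min=0.0)


def random_label_grid(rng: np.random.Generator, max_side: int = 6, max_levels: int = 4):
    """Random small label grid with holes (0 = outside ROI)."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    ng = int(rng.integers(1, max_levels + 1))
    labels = rng.integers(0, ng + 1, size=shape)
    if not (labels > 0).any():
        labels.flat[0] = 1
    return labels, ng


@pytest.fixture(scope="session")
def phantom_pair():
    """One preprocessed patient ear (resampled + normalized), session-wide."""
    from otoradiomics.pipeline import preprocess_ear

    vol, seg = generate_phantom(
        PhantomParams(), "patient", ClassEffect(), DEFAULT_CENTERS[0], seed=42
    )
    return preprocess_ear(vol, seg)


@pytest.fixture(scope="session")
def phantom_features(phantom_pair):
    from otoradiomics.features import extract_all

    img, mask = phantom_pair
    return extract_all(img, mask)
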