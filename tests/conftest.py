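import numpy as np
import pytest

import wsifusion as w
from wsifusion.pipeline import synthetic_study_config

COHORT_SEED = 11
N_PER_CLASS = 8


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """Seeded 16-slide synthetic cohort shared across the session."""
    root = tmp_path_factory.mktemp("cohort")
    w.make_cohort(N_PER_CLASS, seed=COHORT_SEED, out_dir=root)
    return root


@pytest.fixture(scope="session")
def cohort_manifest(cohort_dir):
    return cohort_dir / "manifest.csv"


@pytest.fixture(scope="session")
def study_config():
    return synthetic_study_config(seed=1, ratios=(0.5, 0.25, 0.25))


@pytest.fixture(scope="session")
def men_slide():
    return w.generate_slide(w.SlideSpec("MEN", seed=41, base_size=1024))


@pytest.fixture(scope="session")
def sft_slide():
    return w.generate_slide(w.SlideSpec("SFT", seed=42, base_size=1024))


def tissue_patches(pyramid, truth, size=64, n=20, min_cover=0.95, seed=0):
    """Level-0 windows that sit (almost) fully inside the tissue mask."""
    rng = np.random.default_rng(seed)
    h, w_ = truth.tissue_mask.shape
    out = []
    tries = 0
    while len(out) < n and tries < 50 * n:
        x = int(rng.integers(0, w_ - size))
        y = int(rng.integers(0, h - size))
        tries += 1
        if truth.tissue_mask[y : y + size, x : x + size].mean() >= min_cover:
            out.append(pyramid.levels[0][y : y + size, x : x + size])
    if len(out) < n:
        raise RuntimeError("could not sample enough tissue patches")
    return out
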