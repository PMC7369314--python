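"""Shared fixtures: synthetic image batches reused across counting tests."""

from __future__ import annotations

import numpy as np
import pytest

from dgquant.counting import CountParams, count_cells
from dgquant.synth import ImageSpec, generate_micrograph


def make_suite(n_images: int):
    """Micrographs with true cell numbers spanning 5-60, defaults otherwise."""
    suite = []
    for seed in range(1, n_images + 1):
        rng = np.random.default_rng(seed)
        n_cells = int(rng.integers(5, 61))
        image, roi, truth = generate_micrograph(ImageSpec(n_cells=n_cells, seed=seed))
        suite.append((image, roi, truth))
    return suite


@pytest.fixture(scope="session")
def image_suite_50():
    """50 default-spec micrographs (gradient, noise, artifacts), seeds 1-50."""
    return make_suite(50)


@pytest.fixture(scope="session")
def counts_4_and_5(image_suite_50):
    """Counts of the first 24 suite images at 4 and 5 subtraction passes."""
    c4, c5, true = [], [], []
    for image, roi, truth in image_suite_50[:24]:
        c4.append(count_cells(image, roi, CountParams(n_subtractions=4)).n_cells)
        c5.append(count_cells(image, roi, CountParams(n_subtractions=5)).n_cells)
        true.append(truth.n_cells)
    return np.array(c4), np.array(c5), np.array(true)
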