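"""Shared fixtures: phantoms and a trained classifier, built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from handquant.pipeline import RunConfig, train_on_phantoms
from handquant.synthetic import PhantomSpec, generate_hand_phantom

# seeds reserved for classifier training; test phantoms use other seeds
TRAIN_SEEDS = (100, 101, 102)


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def trained_classifier(run_config):
    return train_on_phantoms(TRAIN_SEEDS, run_config)


@pytest.fixture(scope="session")
def default_phantom():
    """Default-noise phantom with Dixon pair and truth (seed 7)."""
    return generate_hand_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Noise-free phantom with the default bias field (seed 1)."""
    return generate_hand_phantom(PhantomSpec(seed=1, noise_sd=0.0, dixon_noise_sd=0.0))


@pytest.fixture(scope="session")
def unbiased_phantom():
    """Default-noise phantom with no bias field applied (seed 2)."""
    return generate_hand_phantom(PhantomSpec(seed=2, bias_amplitude=0.0))


def probe_points(truth):
    """Physical probe points spanning the Dixon volume, for comparing
    rigid transforms by their action."""
    img = truth.dixon_labels
    ns, nr, nc = img.data.shape
    dx, dy, dz = img.spacing
    x0, y0, z0 = img.origin
    return [
        (x0, y0, z0),
        (x0 + (nc - 1) * dx, y0 + (nr - 1) * dy, z0 + (ns - 1) * dz),
        (x0 + 0.5 * (nc - 1) * dx, y0 + 0.5 * (nr - 1) * dy, z0 + 0.5 * (ns - 1) * dz),
        (x0 + (nc - 1) * dx, y0, z0 + (ns - 1) * dz),
        (x0, y0 + (nr - 1) * dy, z0),
    ]
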