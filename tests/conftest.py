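"""Shared fixtures: phantoms, atlas sets and one segmented subject.

Heavy registration-based fixtures are session-scoped so several test
modules can share a single multi-atlas segmentation run.
"""

import numpy as np
import pytest

from mamvol.atlas_fusion import AtlasSet, segment_mb
from mamvol.phantom_forge import (
    PhantomSpec,
    build_phantom,
    ground_truth_labels,
    make_atlas_set,
)


@pytest.fixture(scope="session")
def clean_spec():
    """Noise- and bias-free default phantom spec."""
    return PhantomSpec(noise_sd=0.0, bias_amplitude=0.0, seed=11)


@pytest.fixture(scope="session")
def clean_phantom(clean_spec):
    return build_phantom(clean_spec)


@pytest.fixture(scope="session")
def base_spec():
    """Default (noisy) phantom spec used for the synthetic population."""
    return PhantomSpec(seed=100)


@pytest.fixture(scope="session")
def atlas_samples(base_spec):
    return make_atlas_set(base_spec, k=5, seed=7)


@pytest.fixture(scope="session")
def atlas_set(atlas_samples):
    return AtlasSet(tuple(atlas_samples))


@pytest.fixture(scope="session")
def held_out_subject(base_spec):
    """One perturbed subject with analytic ground truth at 0.5 mm."""
    sample = make_atlas_set(base_spec, k=1, seed=99)[0]
    gt = ground_truth_labels(base_spec, sample, target_mm=0.5)
    return sample, gt


@pytest.fixture(scope="session")
def segmented_subject(held_out_subject, atlas_set):
    sample, gt = held_out_subject
    result = segment_mb(sample.image, atlas_set)
    return sample, gt, result


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
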