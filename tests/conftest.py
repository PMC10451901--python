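"""Shared fixtures.  The session-scoped phantom and workflow fixtures are
expensive (tens of seconds) and deliberately shared across test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from historeg.core import Volume
from historeg.phantom import generate_phantom
from historeg.workflow import run_workflow


@pytest.fixture(scope="session")
def study_default():
    """One default-parameter phantom (seed 1): the standard study
    conditions."""
    return generate_phantom(seed=1)


@pytest.fixture(scope="session")
def workflow_default(study_default):
    """Estimated five-step workflow on the default phantom."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_workflow(study_default)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_volume(rng, shape=(16, 17, 18), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return Volume(rng.normal(size=shape), np.asarray(spacing), np.asarray(origin))


@pytest.fixture()
def smooth_volume(rng):
    """A smooth random volume with non-trivial geometry, for resampling
    tests where interpolation error must stay small."""
    from scipy import ndimage

    vox = ndimage.gaussian_filter(rng.normal(size=(24, 22, 20)), 2.0)
    return Volume(vox, (1.5, 1.0, 2.0), (-10.0, -5.0, -12.0))
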