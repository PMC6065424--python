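"""Shared fixtures: deterministic patch suites and small phantom runs."""

from __future__ import annotations

import numpy as np
import pytest

from sff.phantom import (
    Blob,
    PhantomConfig,
    generate_cine,
    generate_patch_suite,
)
from sff.spectral import KernelParams


@pytest.fixture(scope="session")
def patch_suite():
    return generate_patch_suite(60, size=(9, 9), seed=7)


@pytest.fixture(scope="session")
def default_params():
    return KernelParams()


@pytest.fixture(scope="session")
def small_cine():
    """A tiny no-motion accumulation run used by several integration tests."""
    cfg = PhantomConfig(
        shape=(48, 48),
        n_frames=8,
        blobs=[Blob(center=(30.0, 24.0), radius=6.0, peak_amplitude=0.3, rate=0.2)],
        artifacts=[],
        motion="none",
        gain_jitter_std=0.0,
        seed=11,
    )
    return generate_cine(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
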