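"""Shared fixtures: small masks, synthetic cohorts, and planted SRM data."""

from __future__ import annotations

import numpy as np
import pytest

import funcsearchlight as fs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture(scope="session")
def cube_mask():
    """Solid 9x9x9 mask: has a genuine radius-3 interior center."""
    return fs.solid_mask(9, 9, 9)


@pytest.fixture(scope="session")
def small_mask():
    return fs.solid_mask(5, 5, 5)


@pytest.fixture(scope="session")
def planted_srm():
    """Three subjects sharing a planted rank-5 response with small noise."""
    rng = np.random.default_rng(11)
    k, v, t = 5, 40, 60
    shared = rng.standard_normal((k, t))
    data, bases = [], []
    for _ in range(3):
        w, _ = np.linalg.qr(rng.standard_normal((v, k)))
        bases.append(w)
        data.append(w @ shared + 0.01 * rng.standard_normal((v, t)))
    return data, bases, shared


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small simulated cohort used by several integration tests."""
    mask = fs.solid_mask(8, 8, 8)
    spec = fs.SimulationSpec(
        mask=mask, n_subjects=3, t=80, fwhm_voxels=0.5, n_signal_voxels=32, seed=5
    )
    bolds, truths, features = fs.simulate_cohort(spec)
    return spec, bolds, truths, features
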