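"""Shared fixtures: small, fast phantoms used across the suite."""

from dataclasses import replace

import numpy as np
import pytest

from retinodex import phantom


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="session")
def small_cryo_cfg() -> phantom.EyePhantomConfig:
    """An 80^3 eye phantom: same shell proportions, desk-scale size."""
    return phantom.EyePhantomConfig(
        eye_diameter_um=800.0, shell_outer_radius_um=350.0,
        shell_thickness_um=60.0, nadh_mean=92.0, fad_mean=100.0,
        noise_cv=0.02, seed=11)


@pytest.fixture()
def small_cryo_factory(small_cryo_cfg):
    def make(**overrides):
        return phantom.make_cryo_phantom(replace(small_cryo_cfg, **overrides))
    return make


@pytest.fixture(scope="session")
def oct_cfg() -> phantom.OctPhantomConfig:
    """Narrower B-scan phantom (700 A-scans) for fast repeated analysis."""
    base = phantom.oct_profile("PBM-p30")
    return replace(base, n_ascans=700, onh_center=350, seed=7)


@pytest.fixture(scope="session")
def erg_cfg() -> phantom.ErgPhantomConfig:
    return phantom.ErgPhantomConfig(noise_sd=0.0, seed=5)
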