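"""Shared fixtures.

Expensive full-size simulations are session-scoped and reused across test
modules; everything is generated programmatically from seeds.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from histoqa import (
    CalibrationState,
    PhantomSpec,
    TreatmentPlan,
    apply_treatment,
    build_phantom,
    plan_helical_path,
    simulate_cbct,
)
from histoqa.pipeline import ImagingParams


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def imaging() -> ImagingParams:
    return ImagingParams()


@pytest.fixture(scope="session")
def phantom(default_spec):
    """Noiseless default phantom volume and target-truth mask."""
    return build_phantom(default_spec)


@pytest.fixture(scope="session")
def pre_cbct(phantom, imaging):
    truth, _ = phantom
    return simulate_cbct(truth, imaging.psf_sigma_mm, imaging.noise_sd, seed=101)


@pytest.fixture(scope="session")
def complete_treatment(phantom, pre_cbct, imaging):
    """Centred 28 mm treatment with zero calibration error: returns
    (pre, post, treated_truth)."""
    truth, _ = phantom
    plan = TreatmentPlan(center_mm=(25.0, 25.0, 25.0), diameter_mm=28.0)
    path = plan_helical_path(plan)
    post_truth, treated = apply_treatment(truth, path, CalibrationState(), seed=102)
    post = simulate_cbct(post_truth, imaging.psf_sigma_mm, imaging.noise_sd, seed=103)
    return pre_cbct, post, treated


@pytest.fixture(scope="session")
def shifted_treatment(phantom, pre_cbct, imaging):
    """28 mm treatment delivered with a hidden (0, 0, -2.4) mm offset."""
    truth, _ = phantom
    plan = TreatmentPlan(center_mm=(25.0, 25.0, 25.0), diameter_mm=28.0)
    path = plan_helical_path(plan)
    post_truth, treated = apply_treatment(
        truth, path, CalibrationState((0.0, 0.0, -2.4)), seed=104
    )
    post = simulate_cbct(post_truth, imaging.psf_sigma_mm, imaging.noise_sd, seed=105)
    return pre_cbct, post, treated


@pytest.fixture(scope="session")
def flat_spec(default_spec) -> PhantomSpec:
    """Zero-contrast phantom spec (layer-free volume)."""
    return replace(default_spec, intensity_high=default_spec.intensity_low)
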