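"""Synthetic multi-layered phantom generation and a CBCT imaging surrogate.

The phantom emulates an agar block with alternating thin high-attenuation
(barium-doped) and thick low-attenuation layers, and an embedded layered
sphere whose layer stack is phase-shifted relative to the outer block. The
phase mismatch produces an intensity discontinuity at the sphere boundary,
which is what makes the target visible (and segmentable) on the simulated
cone-beam CT image.

Layer geometry is periodic along Z (the direction of ultrasound
propagation) with period ``low_layer_thickness_mm + high_layer_thickness_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import ndimage

from .grid import BinaryMask, Volume

__all__ = ["PhantomSpec", "build_phantom", "simulate_cbct"]


@dataclass
class PhantomSpec:
    """Geometric and intensity description of a layered phantom.

    Defaults reproduce the study conditions: a 50 mm cube of alternating
    ~4 mm low-attenuation and ~1 mm high-attenuation layers with an embedded
    28 mm layered sphere whose layer stack is offset by half a layer period.

    Attenuation is in arbitrary units, linear in barium concentration;
    ``intensity_low``/``intensity_high`` default to 20/220 which, combined
    with the default imaging noise, yields treatment-zone SDNRs in the low
    single digits as observed for this phantom class.
    """

    outer_shape: str = "cube"  # "cube" or "cylinder"
    outer_dims_mm: Tuple[float, float, float] = (50.0, 50.0, 50.0)
    low_layer_thickness_mm: float = 4.0
    high_layer_thickness_mm: float = 1.0
    target_diameter_mm: float = 28.0
    target_center_mm: Tuple[float, float, float] = (25.0, 25.0, 25.0)
    target_layer_phase_mm: float = 2.5
    outer_layer_phase_mm: float = 0.0
    intensity_low: float = 20.0
    intensity_high: float = 220.0
    spacing_mm: float = 0.5
    containment_margin_mm: float = 2.0

    @property
    def layer_period_mm(self) -> float:
        return self.low_layer_thickness_mm + self.high_layer_thickness_mm

    def validate(self) -> None:
        if self.outer_shape not in ("cube", "cylinder"):
            raise ValueError(f"unknown outer_shape {self.outer_shape!r}")
        if self.low_layer_thickness_mm <= 0 or self.high_layer_thickness_mm <= 0:
            raise ValueError("layer thicknesses must be positive")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if self.target_diameter_mm <= 0:
            raise ValueError("target_diameter_mm must be positive")
        r = self.target_diameter_mm / 2.0
        c = np.asarray(self.target_center_mm, dtype=float)
        dims = np.asarray(self.outer_dims_mm, dtype=float)
        m = self.containment_margin_mm
        if self.outer_shape == "cube":
            lo_ok = np.all(c - r >= m)
            hi_ok = np.all(c + r <= dims - m)
            contained = bool(lo_ok and hi_ok)
        else:  # cylinder: circular cross-section in XY, flat faces along Z
            rad = min(dims[0], dims[1]) / 2.0
            axis = np.array([dims[0] / 2.0, dims[1] / 2.0])
            in_plane = np.linalg.norm(c[:2] - axis) + r <= rad - m
            in_z = (c[2] - r >= m) and (c[2] + r <= dims[2] - m)
            contained = bool(in_plane and in_z)
        if not contained:
            raise ValueError(
                f"target sphere (center {tuple(c)}, diameter "
                f"{self.target_diameter_mm} mm) not contained in the "
                f"{self.outer_shape} outer phantom {tuple(dims)} with a "
                f"{m} mm margin"
            )


def _layer_intensity(
    z_mm: np.ndarray, phase_mm: float, spec: PhantomSpec
) -> np.ndarray:
    """Periodic layer intensity along Z: low for the first
    ``low_layer_thickness_mm`` of each period, high for the remainder."""
    frac = np.mod(z_mm - phase_mm, spec.layer_period_mm)
    return np.where(
        frac >= spec.low_layer_thickness_mm, spec.intensity_high, spec.intensity_low
    )


def build_phantom(spec: PhantomSpec) -> Tuple[Volume, BinaryMask]:
    """Rasterize a layered phantom with its embedded layered spherical target.

    Returns
    -------
    volume : Volume
        Noiseless ground-truth attenuation volume. Outside a cylindrical
        outer shape the background is 0 (water bath).
    target_truth : BinaryMask
        True for every voxel whose centre lies within
        ``target_diameter_mm / 2`` of ``target_center_mm``.
    """
    spec.validate()
    dims = np.asarray(spec.outer_dims_mm, dtype=float)
    sp = spec.spacing_mm
    n = np.maximum(1, np.round(dims / sp)).astype(int)
    origin = np.full(3, sp / 2.0)

    x = origin[0] + sp * np.arange(n[0])
    y = origin[1] + sp * np.arange(n[1])
    z = origin[2] + sp * np.arange(n[2])

    outer = _layer_intensity(z, spec.outer_layer_phase_mm, spec)[None, None, :]
    inner = _layer_intensity(
        z, spec.outer_layer_phase_mm + spec.target_layer_phase_mm, spec
    )[None, None, :]

    c = np.asarray(spec.target_center_mm, dtype=float)
    dx2 = (x - c[0])[:, None, None] ** 2
    dy2 = (y - c[1])[None, :, None] ** 2
    dz2 = (z - c[2])[None, None, :] ** 2
    r2 = (spec.target_diameter_mm / 2.0) ** 2
    in_target = dx2 + dy2 + dz2 <= r2

    values = np.where(in_target, inner, outer).astype(float)

    if spec.outer_shape == "cylinder":
        rad = min(dims[0], dims[1]) / 2.0
        axis = np.array([dims[0] / 2.0, dims[1] / 2.0])
        in_plane = (x - axis[0])[:, None] ** 2 + (y - axis[1])[None, :] ** 2
        inside = in_plane <= rad**2
        values = np.where(inside[:, :, None], values, 0.0)

    vol = Volume(values, sp, origin)
    truth = BinaryMask(in_target, sp, origin)
    return vol, truth


def simulate_cbct(
    vol: Volume, psf_sigma_mm: float, noise_sd: float, seed: int
) -> Volume:
    """CBCT acquisition surrogate: isotropic Gaussian blur plus additive
    zero-mean Gaussian noise of standard deviation ``noise_sd``.

    The blur kernel is normalized (mean preserving); noise is added after
    the blur so the output noise SD equals ``noise_sd`` exactly in
    expectation. Deterministic given ``seed``. No cone-beam reconstruction
    artifacts are modelled.
    """
    if psf_sigma_mm < 0:
        raise ValueError(f"psf_sigma_mm must be >= 0, got {psf_sigma_mm}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    out = vol.values.astype(float)
    if psf_sigma_mm > 0:
        # periodic boundary keeps the blur kernel exactly mean-preserving
        out = ndimage.gaussian_filter(
            out, sigma=psf_sigma_mm / vol.spacing_mm, mode="wrap"
        )
    else:
        out = out.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return Volume(out, vol.spacing_mm, vol.origin_mm.copy())
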