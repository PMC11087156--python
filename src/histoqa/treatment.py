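"""Histotripsy treatment simulation.

A spherical treatment is realized by sweeping an ellipsoidal cavitation
bubble cloud (default 3 x 3 x 6 mm, long axis along Z) along a helical path
through the planned volume. Treatment homogenizes the alternating layers
inside the swept region — by default to the mean pre-treatment intensity of
the treated material (complete homogenization, as achieved by treating the
volume twice) — which is how the treatment zone becomes visible on
post-treatment CBCT.

Two distinct error mechanisms are modelled:

* calibration error — a hidden ``true_offset_mm`` displacing every delivered
  cloud from its assumed position (the analysis pipeline never reads it);
* mistargeting — an intentional ``lateral_shift_mm`` applied to the plan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .grid import BinaryMask, Volume

__all__ = [
    "TreatmentPlan",
    "BubbleCloudSpec",
    "CalibrationState",
    "CloudPath",
    "plan_helical_path",
    "apply_treatment",
    "rasterize_cloud_union",
]


@dataclass
class TreatmentPlan:
    """Planned spherical treatment: centre and diameter, plus an optional
    intentional lateral shift used in mistarget scenarios."""

    center_mm: Tuple[float, float, float]
    diameter_mm: float = 28.0
    lateral_shift_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")

    @property
    def effective_center_mm(self) -> np.ndarray:
        return np.asarray(self.center_mm, float) + np.asarray(
            self.lateral_shift_mm, float
        )


@dataclass
class BubbleCloudSpec:
    """Ellipsoidal cavitation cloud; long axis along Z (beam direction)."""

    semi_axes_mm: Tuple[float, float, float] = (1.5, 1.5, 3.0)

    def __post_init__(self) -> None:
        a = np.asarray(self.semi_axes_mm, float)
        if np.any(a <= 0):
            raise ValueError("all semi-axes must be positive")
        if not (a[2] >= a[0] and a[2] >= a[1]):
            raise ValueError("cloud long axis must be Z")


@dataclass
class CalibrationState:
    """Ground-truth displacement of the delivered cloud from the assumed
    (planned) location. Analysis code must never read this."""

    true_offset_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.true_offset_mm, float)
        if not np.all(np.isfinite(v)):
            raise ValueError("true_offset_mm must be finite")


@dataclass
class CloudPath:
    """Ordered sequence of bubble-cloud centre positions (mm)."""

    centers_mm: np.ndarray
    cloud: BubbleCloudSpec = field(default_factory=BubbleCloudSpec)

    def __post_init__(self) -> None:
        self.centers_mm = np.atleast_2d(np.asarray(self.centers_mm, float))
        if self.centers_mm.shape[1] != 3:
            raise ValueError("centers_mm must be (N, 3)")

    def __len__(self) -> int:
        return self.centers_mm.shape[0]

    def translated(self, shift_mm) -> "CloudPath":
        return CloudPath(self.centers_mm + np.asarray(shift_mm, float), self.cloud)


# Packing constants for the helical sweep. The prototype system's actual
# packing is unknown; these values are chosen so the ellipsoid union covers
# >= 99% of the planned sphere while the composite extent stays within
# about half a voxel of the planned diameter along the measurement axes.
_Z_PITCH_MM = 2.0  # helix rise per turn
_RING_SPACING_MM = 1.25  # radial distance between concentric helices
_ARC_STEP_MM = 1.0  # max in-plane spacing of consecutive centres


def plan_helical_path(plan: TreatmentPlan, cloud: BubbleCloudSpec | None = None) -> CloudPath:
    """Plan a helical bubble-cloud trajectory covering the planned sphere.

    The path is a stack of concentric helices of decreasing radius (fixed Z
    pitch), outermost first, plus an axial column of centres. Each ring's Z
    extent follows the sphere's inscribed height, and each helix finishes
    with a closing circle at both ends (otherwise the last turn leaves a
    full-pitch vertical gap at some angles, uncovering the sphere's
    shoulder). A plan smaller than the cloud's short axis degenerates to a
    single centre at the plan centre.
    """
    cloud = cloud or BubbleCloudSpec()
    a, _, c = cloud.semi_axes_mm
    R = plan.diameter_mm / 2.0
    center = plan.effective_center_mm
    if plan.diameter_mm < 2 * a:
        return CloudPath(center[None, :], cloud)

    pts: List[np.ndarray] = []
    ring = R - a
    theta0 = 0.0
    while ring > _RING_SPACING_MM / 2.0:
        z_half = max(0.0, math.sqrt(max(R * R - ring * ring, 0.0)) - c)
        n_per_turn = max(6, int(math.ceil(2 * math.pi * ring / _ARC_STEP_MM)))
        theta_circle = theta0 + 2 * math.pi * np.arange(n_per_turn) / n_per_turn
        if z_half > 0:
            n_turns = max(1, int(math.ceil(2 * z_half / _Z_PITCH_MM)))
            n_steps = n_per_turn * n_turns
            i = np.arange(n_steps + 1)
            theta = theta0 + 2 * math.pi * i / n_per_turn
            z = np.linspace(-z_half, z_half, n_steps + 1)
            pts.append(np.column_stack([ring * np.cos(theta), ring * np.sin(theta), z]))
            for z_end in (-z_half, z_half):
                pts.append(
                    np.column_stack(
                        [
                            ring * np.cos(theta_circle),
                            ring * np.sin(theta_circle),
                            np.full(n_per_turn, z_end),
                        ]
                    )
                )
        else:
            pts.append(
                np.column_stack(
                    [
                        ring * np.cos(theta_circle),
                        ring * np.sin(theta_circle),
                        np.zeros(n_per_turn),
                    ]
                )
            )
        theta0 += 2.399963  # golden-angle stagger between rings
        ring -= _RING_SPACING_MM

    # axial column so the poles are reached without Z overshoot
    z_top = R - c
    if z_top > 0:
        n_axis = int(math.floor(2 * z_top / _Z_PITCH_MM)) + 1
        z_axis = np.linspace(-z_top, z_top, max(n_axis, 2))
    else:
        z_axis = np.array([0.0])
    pts.append(np.column_stack([np.zeros_like(z_axis), np.zeros_like(z_axis), z_axis]))

    centers = np.vstack(pts) + center
    return CloudPath(centers, cloud)


def rasterize_cloud_union(
    path: CloudPath, like: Volume | BinaryMask, offset_mm=(0.0, 0.0, 0.0)
) -> BinaryMask:
    """Voxelize the union of cloud ellipsoids at ``path`` positions (plus an
    optional global offset) on the grid of ``like``, by voxel-centre test."""
    sp = like.spacing_mm
    origin = like.origin_mm
    shape = like.shape
    semi = np.asarray(path.cloud.semi_axes_mm, float)
    out = np.zeros(shape, dtype=bool)
    half = np.ceil(semi / sp).astype(int) + 1
    centers = path.centers_mm + np.asarray(offset_mm, float)
    for cen in centers:
        ci = (cen - origin) / sp
        lo = np.maximum(np.floor(ci - half).astype(int), 0)
        hi = np.minimum(np.ceil(ci + half).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        ax = [origin[a] + sp * np.arange(lo[a], hi[a]) - cen[a] for a in range(3)]
        q = (
            (ax[0][:, None, None] / semi[0]) ** 2
            + (ax[1][None, :, None] / semi[1]) ** 2
            + (ax[2][None, None, :] / semi[2]) ** 2
        )
        out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= q <= 1.0
    return BinaryMask(out, sp, origin.copy())


def apply_treatment(
    pre: Volume,
    path: CloudPath,
    calib: CalibrationState | None = None,
    mixing_window_mm: float = 5.0,
    seed: int = 0,
    homogenate_noise_sd: float = 0.0,
    full_homogenization: bool = True,
) -> Tuple[Volume, BinaryMask]:
    """Homogenize the layered phantom inside the swept cloud volume.

    The delivered cloud positions are the planned ``path`` displaced by the
    hidden calibration offset. Layer mixing replaces each treated voxel by
    a mean of the pre-treatment intensities: a single sweep mixes over a Z
    window of ``mixing_window_mm`` (one layer period by default, so the
    local homogenate is the thickness-weighted layer mean); the study
    protocol treats every phantom twice to ensure *adequate*
    homogenization, and repeated mixing converges to the mean over the
    whole treated region. ``full_homogenization`` (the default) applies
    that converged state — the fixed point of windowed mixing, which makes
    a second ``apply_treatment`` pass exactly idempotent — while ``False``
    gives the single-sweep windowed mix. Outside the treated region the
    volume is returned unchanged; imaging noise is applied afterwards by
    the CBCT surrogate, so ``homogenate_noise_sd`` defaults to 0.

    Returns the post-treatment volume and the ground-truth treated mask.
    """
    if len(path) == 0:
        raise ValueError("path must be nonempty")
    calib = calib or CalibrationState()
    offset = np.asarray(calib.true_offset_mm, float)

    lo_world = pre.origin_mm - pre.spacing_mm / 2.0
    hi_world = pre.origin_mm + pre.spacing_mm * (np.array(pre.shape) - 0.5)
    delivered = path.centers_mm + offset
    if np.any(delivered < lo_world) or np.any(delivered > hi_world):
        raise ValueError("delivered cloud path extends outside the volume bounds")

    treated = rasterize_cloud_union(path, pre, offset_mm=offset)

    vals = pre.values.astype(float)
    if full_homogenization:
        homogenate = float(vals[treated.values].mean())
        post = np.where(treated.values, homogenate, vals)
    else:
        win = max(1, int(round(mixing_window_mm / pre.spacing_mm)))
        mixed = ndimage.uniform_filter1d(vals, size=win, axis=2, mode="nearest")
        post = np.where(treated.values, mixed, vals)
    if homogenate_noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, homogenate_noise_sd, size=post.shape)
        post = np.where(treated.values, post + noise, post)
    return Volume(post, pre.spacing_mm, pre.origin_mm.copy()), treated
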