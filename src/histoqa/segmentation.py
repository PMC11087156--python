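"""Automated segmentation surrogates.

The physical study contoured treatment zones and targets manually; here
both are extracted deterministically so results can be tested against
simulator ground truth. The treatment zone is segmented from the pre/post
difference image (the two scans share one grid because the set-up is not
moved between acquisitions); the intact spherical target is segmented from
the pre-treatment scan by detecting the in-plane intensity discontinuity
created by the phase mismatch between target and outer layer stacks, then
fitting a sphere to the detected edge shell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .grid import BinaryMask, Volume

__all__ = [
    "SegmentationParams",
    "SegmentationError",
    "NoTreatmentDetectedError",
    "TargetNotFoundError",
    "segment_treatment_zone",
    "segment_target",
]


class SegmentationError(RuntimeError):
    pass


class NoTreatmentDetectedError(SegmentationError):
    """Raised when the pre/post difference carries no treatment signal."""


class TargetNotFoundError(SegmentationError):
    """Raised when no target edge is detectable (e.g. zero layer contrast)."""


@dataclass
class SegmentationParams:
    """Knobs for the automated segmentation surrogate.

    ``smooth_sigma_mm`` blends the alternating-layer difference signal into
    a solid blob before thresholding (default roughly half a layer period);
    components are 6-connected and the winning component is morphologically
    closed with a 1-voxel ball. With ``refine_shape='sphere'`` (default)
    the treatment-zone mask is regularized to the sphere that best explains
    the difference image — the counterpart of a human contouring a planned
    spherical treatment as a smooth closed boundary; ``grad_sigma_mm``
    controls the smoothing used for that boundary-gradient shell.
    """

    smooth_sigma_mm: float = 2.0
    threshold_method: str = "otsu"  # "otsu" or "fixed"
    fixed_threshold: Optional[float] = None
    min_component_voxels: int = 500
    closing_radius_vox: int = 1
    refine_shape: str = "sphere"  # "sphere" or "none"
    grad_sigma_mm: float = 1.0

    def validate(self) -> None:
        if self.smooth_sigma_mm < 0 or self.grad_sigma_mm < 0:
            raise ValueError("smoothing sigmas must be >= 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed_threshold required with threshold_method='fixed'")
        if self.refine_shape not in ("sphere", "none"):
            raise ValueError(f"unknown refine_shape {self.refine_shape!r}")
        if self.min_component_voxels < 1 or self.closing_radius_vox < 0:
            raise ValueError("min_component_voxels >= 1, closing_radius_vox >= 0")


_CONN6 = ndimage.generate_binary_structure(3, 1)


def _largest_component(bw: np.ndarray) -> Tuple[np.ndarray, int]:
    labels, n = ndimage.label(bw, structure=_CONN6)
    if n == 0:
        return np.zeros_like(bw, dtype=bool), 0
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = int(counts.argmax())
    return labels == best, int(counts[best])


def segment_treatment_zone(
    pre: Volume, post: Volume, params: SegmentationParams | None = None
) -> BinaryMask:
    """Segment the homogenized treatment zone from a pre/post image pair.

    Detection: the smoothed absolute difference image is thresholded (Otsu
    by default) and the largest 6-connected component kept. The difference
    signal is locally unreliable where the blurred target-edge band
    resembles the homogenate, so by default the mask is then regularized to
    a sphere (``refine_shape='sphere'``): the centre comes from a weighted
    least-squares fit to the difference image's boundary-gradient shell
    (strong, symmetric evidence of the zone surface) and the radius is
    volume-matched to the detected component. ``refine_shape='none'``
    returns the morphologically closed raw component instead.

    Raises :class:`NoTreatmentDetectedError` when there is no treatment
    signal — identical inputs, an empty threshold result, a largest
    component below ``min_component_voxels``, or a candidate zone whose
    mean difference does not rise above the noise floor.
    """
    params = params or SegmentationParams()
    params.validate()
    pre.require_same_grid(post)
    sp = pre.spacing_mm

    diff = np.abs(post.values.astype(float) - pre.values.astype(float))
    if params.smooth_sigma_mm > 0:
        diff_s = ndimage.gaussian_filter(
            diff, sigma=params.smooth_sigma_mm / sp, mode="nearest"
        )
    else:
        diff_s = diff

    if not np.any(diff_s > 0):
        raise NoTreatmentDetectedError("pre and post images are identical")

    if params.threshold_method == "fixed":
        thr = float(params.fixed_threshold)
        comp, size = _largest_component(diff_s > thr)
    else:
        # two-pass Otsu: a global pass finds the zone, a second pass inside
        # the zone's neighbourhood rebalances the foreground/background
        # classes (global Otsu is biased by the dominant background)
        comp, size = _largest_component(diff_s > float(threshold_otsu(diff_s)))
        if size > 0:
            idx = np.argwhere(comp)
            pad = int(round(5.0 / sp))
            lo = np.maximum(idx.min(axis=0) - pad, 0)
            hi = np.minimum(idx.max(axis=0) + pad + 1, comp.shape)
            thr = float(threshold_otsu(diff_s[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]))
            comp, size = _largest_component(diff_s > thr)
    if size < params.min_component_voxels:
        raise NoTreatmentDetectedError(
            f"largest difference component has {size} voxels "
            f"(< {params.min_component_voxels}); no treatment detected"
        )

    # the zone must stand clear of the noise floor of the difference image
    robust_sigma = float(np.median(diff)) / 0.6745 if np.median(diff) > 0 else 0.0
    if robust_sigma > 0 and float(diff[comp].mean()) < 2.0 * robust_sigma:
        raise NoTreatmentDetectedError(
            "candidate treatment zone indistinguishable from noise"
        )

    if params.refine_shape == "sphere":
        return _sphere_refined_zone(pre, diff, comp, size, params)

    if params.closing_radius_vox > 0:
        comp = ndimage.binary_closing(comp, structure=ball(params.closing_radius_vox))
    return BinaryMask(comp, sp, pre.origin_mm.copy())


# the surface-evidence band around the detected component's boundary: the
# true zone surface can only lie at or outward of the threshold-eroded
# boundary, while spurious difference gradients (the target's edge band)
# lie deeper inside the component
_SHELL_BAND_INNER_MM = 1.0
_SHELL_BAND_OUTER_MM = 2.5
_COMP_TRIM_MARGIN_MM = 0.75  # half the cloud in-plane semi-axis


def _sphere_refined_zone(
    pre: Volume,
    diff: np.ndarray,
    comp: np.ndarray,
    size: int,
    params: SegmentationParams,
) -> BinaryMask:
    """Sphere regularization of the treatment zone (see
    :func:`segment_treatment_zone`)."""
    sp = pre.spacing_mm
    d_in = ndimage.distance_transform_edt(comp, sampling=sp)
    d_out = ndimage.distance_transform_edt(~comp, sampling=sp)
    near = np.where(comp, d_in <= _SHELL_BAND_INNER_MM, d_out <= _SHELL_BAND_OUTER_MM)

    smoothed = diff
    if params.grad_sigma_mm > 0:
        smoothed = ndimage.gaussian_filter(diff, sigma=params.grad_sigma_mm / sp, mode="nearest")
    grad = np.gradient(smoothed, sp)
    gmag = np.sqrt(grad[0] ** 2 + grad[1] ** 2 + grad[2] ** 2)
    shell = (gmag > threshold_otsu(gmag[near])) & near
    pts = pre.origin_mm + sp * np.argwhere(shell)
    wts = gmag[shell]
    center, radius = _fit_sphere(pts, wts)
    for band in (3.0, 2.0, 1.5):  # progressively trimmed refit
        d = np.linalg.norm(pts - center, axis=1)
        keep = np.abs(d - radius) < band
        if keep.sum() < 50:
            break
        center, radius = _fit_sphere(pts[keep], wts[keep])
    # the shell fit locates the centre; the radius is volume-matched to the
    # detected component, and the component itself is kept (union) so real
    # asymmetries of the difference signal are not erased by the sphere.
    # Component protrusions well beyond the fitted
    # sphere cannot be treated material (the swept union is bounded by the
    # planned sphere plus the cloud) and are trimmed as blur spillover.
    radius_vol = (3.0 * size * sp**3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    x, y, z = pre.world_axes()
    d2 = (
        (x - center[0])[:, None, None] ** 2
        + (y - center[1])[None, :, None] ** 2
        + (z - center[2])[None, None, :] ** 2
    )
    keep_comp = comp & (d2 <= (radius_vol + _COMP_TRIM_MARGIN_MM) ** 2)
    return BinaryMask((d2 <= radius_vol**2) | keep_comp, sp, pre.origin_mm.copy())


def _fit_sphere(points: np.ndarray, weights: np.ndarray) -> Tuple[np.ndarray, float]:
    """Weighted algebraic least-squares sphere fit.

    Solves ``|x|^2 = 2 c.x + rho`` for centre ``c`` and ``rho = r^2 - |c|^2``.
    """
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    b = np.sum(points**2, axis=1)
    w = np.sqrt(weights)
    sol, *_ = np.linalg.lstsq(A * w[:, None], b * w, rcond=None)
    center = sol[:3]
    r2 = sol[3] + float(center @ center)
    if r2 <= 0:
        raise TargetNotFoundError("sphere fit degenerate (non-positive radius)")
    return center, float(np.sqrt(r2))


def segment_target(
    pre: Volume,
    approx_center_mm,
    params: SegmentationParams | None = None,
    search_radius_mm: float = 20.0,
) -> BinaryMask:
    """Segment the intact spherical target from a pre-treatment volume.

    Seeded by an approximate centre (the operator-click surrogate). Layer
    stacks inside and outside the target are both constant within any XY
    plane, so the in-plane gradient magnitude is non-zero only on the
    target boundary (where the phase mismatch juxtaposes different layer
    intensities) and from noise. Edge voxels are detected by Otsu
    thresholding of that gradient within the search box; a sphere is fitted
    to them by weighted least squares with two inlier-refinement rounds,
    and the fitted sphere is returned as a voxel mask.

    Raises :class:`TargetNotFoundError` when the fitted edge shell does not
    stand out from the background gradient level (e.g. zero layer contrast).
    """
    params = params or SegmentationParams()
    approx = np.asarray(approx_center_mm, float)
    sp = pre.spacing_mm

    lo = np.maximum(np.floor((approx - search_radius_mm - pre.origin_mm) / sp), 0).astype(int)
    hi = np.minimum(
        np.ceil((approx + search_radius_mm - pre.origin_mm) / sp) + 1,
        pre.shape,
    ).astype(int)
    crop = pre.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(float)
    sm = ndimage.gaussian_filter(crop, sigma=1.0 / sp, mode="nearest")
    gx, gy = np.gradient(sm, sp, axis=(0, 1))
    g = np.hypot(gx, gy)

    thr = float(threshold_otsu(g))
    edge = g > thr
    if edge.sum() < 50:
        raise TargetNotFoundError("too few edge voxels; no detectable target edge")

    idx = np.argwhere(edge)
    pts = pre.origin_mm + sp * (idx + lo)
    wts = g[edge]
    center, radius = _fit_sphere(pts, wts)
    for _ in range(2):  # inlier refinement
        d = np.linalg.norm(pts - center, axis=1)
        keep = np.abs(d - radius) < 2.0
        if keep.sum() < 50:
            raise TargetNotFoundError("sphere fit unsupported by edge voxels")
        center, radius = _fit_sphere(pts[keep], wts[keep])

    if not (2.0 < radius < search_radius_mm):
        raise TargetNotFoundError(f"implausible fitted radius {radius:.1f} mm")

    # edge support check: gradient on the fitted shell must dominate background
    d_all = np.linalg.norm(
        pre.origin_mm + sp * (np.argwhere(np.ones_like(g, dtype=bool)) + lo) - center,
        axis=1,
    ).reshape(g.shape)
    shell = np.abs(d_all - radius) < 1.0
    if not shell.any() or float(g[shell].mean()) < 2.0 * float(np.median(g)):
        raise TargetNotFoundError("fitted sphere has no gradient support")

    x, y, z = pre.world_axes()
    d2 = (
        (x - center[0])[:, None, None] ** 2
        + (y - center[1])[None, :, None] ** 2
        + (z - center[2])[None, None, :] ** 2
    )
    return BinaryMask(d2 <= radius**2, sp, pre.origin_mm.copy())
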