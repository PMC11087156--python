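"""Quantitative QA core: centroids, offsets, diameters, group statistics
and the calibration-refinement rule.

The location estimator throughout is the centroid (first image moment) of
a binary mask in world coordinates. Offsets are signed per-axis
differences (measured minus planned). Group comparisons use two-sided
unpaired t-tests on per-axis offset magnitudes; signed means are retained
because the calibration correction is the signed mean offset on every axis
whose mean magnitude exceeds the refinement threshold (1 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats

from .grid import BinaryMask

__all__ = [
    "OffsetMeasurement",
    "SizeMeasurement",
    "GroupStats",
    "CalibrationCorrection",
    "centroid",
    "measure_offset",
    "measure_diameters",
    "group_stats",
    "refine_calibration",
    "target_to_treatment_distance",
    "round_report",
]

REFINEMENT_THRESHOLD_MM = 1.0


def round_report(x, decimals: int = 1):
    """Reporting-layer rounding to 0.1 mm; never applied internally."""
    return np.round(np.asarray(x, float), decimals)


@dataclass
class OffsetMeasurement:
    """Signed per-axis centroid offset (measured minus planned), in mm."""

    dx_mm: float
    dy_mm: float
    dz_mm: float

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.dx_mm, self.dy_mm, self.dz_mm])

    @property
    def euclidean_mm(self) -> float:
        return float(np.sqrt(self.dx_mm**2 + self.dy_mm**2 + self.dz_mm**2))


@dataclass
class SizeMeasurement:
    """Axis-aligned extents of a mask through its centroid, in mm."""

    diam_x_mm: float
    diam_y_mm: float
    diam_z_mm: float

    def __post_init__(self) -> None:
        if min(self.diam_x_mm, self.diam_y_mm, self.diam_z_mm) < 0:
            raise ValueError("diameters must be non-negative")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.diam_x_mm, self.diam_y_mm, self.diam_z_mm])


@dataclass
class GroupStats:
    """Per-axis summary of a group of offset measurements.

    Means/SDs are kept both signed (as tabulated) and as magnitudes (as
    summarized in prose and used for the before/after comparison). When a
    second group is supplied, ``t_statistic``/``p_value`` hold the per-axis
    two-sided unpaired t-test on offset magnitudes.
    """

    n: int
    mean_per_axis: np.ndarray  # signed
    sd_per_axis: np.ndarray  # signed, sample SD (n-1)
    mean_abs_per_axis: np.ndarray
    sd_abs_per_axis: np.ndarray
    mean_euclidean_mm: float
    sd_euclidean_mm: float
    n_b: Optional[int] = None
    t_statistic: Optional[np.ndarray] = None
    p_value: Optional[np.ndarray] = None


@dataclass
class CalibrationCorrection:
    """Correction (mm) added to the assumed focal location per axis."""

    correction_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.correction_mm = np.asarray(self.correction_mm, float).reshape(3)

    @property
    def is_zero(self) -> bool:
        return bool(np.all(self.correction_mm == 0))


def centroid(mask: BinaryMask) -> np.ndarray:
    """Centroid (first image moment) of a binary mask, in world mm.

    Arithmetic mean of the world coordinates of the centres of all True
    voxels; rejects an empty mask.
    """
    if mask.n_true == 0:
        raise ValueError("centroid of an empty mask is undefined")
    com = ndimage.center_of_mass(mask.values)
    return mask.origin_mm + mask.spacing_mm * np.asarray(com)


def measure_offset(planned_center_mm, mask: BinaryMask) -> OffsetMeasurement:
    """Per-axis signed offsets centroid(mask) - planned_center."""
    c = centroid(mask)
    d = c - np.asarray(planned_center_mm, float)
    return OffsetMeasurement(*d)


def measure_diameters(mask: BinaryMask) -> SizeMeasurement:
    """Extent of the mask along each axis-aligned line through its centroid.

    Mirrors caliper-style manual measurement on orthogonal planes: no
    sub-voxel interpolation, so each value is exact to one voxel. Rejects
    empty or disconnected (6-connectivity) masks.
    """
    if mask.n_true == 0:
        raise ValueError("cannot measure an empty mask")
    _, n = ndimage.label(mask.values, structure=ndimage.generate_binary_structure(3, 1))
    if n != 1:
        raise ValueError(f"mask must be a single connected component, found {n}")
    c_idx = np.asarray(ndimage.center_of_mass(mask.values))
    ci = np.clip(np.round(c_idx).astype(int), 0, np.array(mask.shape) - 1)
    lines = (
        mask.values[:, ci[1], ci[2]],
        mask.values[ci[0], :, ci[2]],
        mask.values[ci[0], ci[1], :],
    )
    ext = []
    for line in lines:
        w = np.flatnonzero(line)
        ext.append(0.0 if w.size == 0 else (w[-1] - w[0] + 1) * mask.spacing_mm)
    return SizeMeasurement(*ext)


def _offsets_array(offsets: Sequence[OffsetMeasurement]) -> np.ndarray:
    return np.array([o.vector for o in offsets], float).reshape(-1, 3)


def group_stats(
    offsets_a: Sequence[OffsetMeasurement],
    offsets_b: Optional[Sequence[OffsetMeasurement]] = None,
    equal_var: bool = True,
) -> GroupStats:
    """Per-axis mean +/- sample SD of a group of offsets; optionally a
    two-sided unpaired t-test per axis against a second group.

    The t-test compares offset magnitudes (Student's equal-variance by
    default; set ``equal_var=False`` for Welch) and requires n >= 2 per
    group. A single group may have n = 1 (a one-phantom calibration run
    still yields usable mean offsets); its SDs are then NaN.
    """
    a = _offsets_array(offsets_a)
    if a.shape[0] < 1:
        raise ValueError("need at least 1 measurement")
    eu = np.linalg.norm(a, axis=1)
    nan3 = np.full(3, np.nan)
    n = a.shape[0]
    out = GroupStats(
        n=n,
        mean_per_axis=a.mean(axis=0),
        sd_per_axis=a.std(axis=0, ddof=1) if n > 1 else nan3.copy(),
        mean_abs_per_axis=np.abs(a).mean(axis=0),
        sd_abs_per_axis=np.abs(a).std(axis=0, ddof=1) if n > 1 else nan3.copy(),
        mean_euclidean_mm=float(eu.mean()),
        sd_euclidean_mm=float(eu.std(ddof=1)) if n > 1 else float("nan"),
    )
    if offsets_b is not None:
        b = _offsets_array(offsets_b)
        if b.shape[0] < 2:
            raise ValueError("need at least 2 measurements per group")
        res = stats.ttest_ind(np.abs(a), np.abs(b), axis=0, equal_var=equal_var)
        out.n_b = b.shape[0]
        out.t_statistic = np.asarray(res.statistic)
        out.p_value = np.asarray(res.pvalue)
    return out


def refine_calibration(
    gstats: GroupStats, threshold_mm: float = REFINEMENT_THRESHOLD_MM
) -> CalibrationCorrection:
    """Calibration-refinement rule: on each axis whose mean offset
    magnitude exceeds ``threshold_mm``, the correction is the mean signed
    offset; other axes are left untouched. An all-zero correction is a
    valid outcome."""
    exceed = gstats.mean_abs_per_axis > threshold_mm
    return CalibrationCorrection(np.where(exceed, gstats.mean_per_axis, 0.0))


def target_to_treatment_distance(
    target_mask: BinaryMask, treatment_mask: BinaryMask
) -> OffsetMeasurement:
    """Per-axis centroid differences, treatment minus target."""
    return measure_offset(centroid(target_mask), treatment_mask)
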