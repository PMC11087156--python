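"""End-to-end study orchestration.

A study group (calibration refinement before/after, undertreatment,
mistarget) is a set of simulated phantoms, each run through the full QA
chain: build phantom -> pre-treatment CBCT -> plan on the segmented target
-> helical treatment with a hidden calibration offset -> post-treatment
CBCT -> segment -> measure offsets, diameters and visibility. Group
statistics and, for the calibration group, the refinement correction are
aggregated into a :class:`StudyReport`.

Randomness is controlled by one explicit seed per phantom; stage seeds are
derived from it, so identical configurations produce identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .grid import BinaryMask, Volume
from .metrics import (
    CalibrationCorrection,
    GroupStats,
    OffsetMeasurement,
    centroid,
    group_stats,
    measure_diameters,
    measure_offset,
    refine_calibration,
    target_to_treatment_distance,
)
from .phantom import PhantomSpec, build_phantom, simulate_cbct
from .segmentation import SegmentationParams, segment_target, segment_treatment_zone
from .treatment import (
    BubbleCloudSpec,
    CalibrationState,
    TreatmentPlan,
    apply_treatment,
    plan_helical_path,
)
from .visibility import (
    EdgeStrengthConfig,
    Roi,
    RoiSet,
    edge_strength,
    measure_rois,
    noise_sd_from_layers,
    sdnr,
)

__all__ = [
    "ImagingParams",
    "StudyConfig",
    "StudyReport",
    "run_single_phantom",
    "run_study",
    "closed_loop_refinement",
    "default_layer_rois",
]

GROUPS = ("pre_refinement", "post_refinement", "undertreatment", "mistarget")

_ROW_COLUMNS = [
    "phantom",
    "seed",
    "status",
    "dx_mm",
    "dy_mm",
    "dz_mm",
    "euclidean_mm",
    "diam_x_mm",
    "diam_y_mm",
    "diam_z_mm",
    "tt_dx_mm",
    "tt_dy_mm",
    "tt_dz_mm",
    "tt_euclidean_mm",
    "sdnr_vs_barium",
    "sdnr_vs_nonbarium",
    "edge_strength",
    "noise_sd",
]


@dataclass
class ImagingParams:
    """CBCT surrogate parameters: blur sigma and additive noise SD."""

    psf_sigma_mm: float = 0.8
    noise_sd: float = 8.0


@dataclass
class StudyConfig:
    """Configuration of one simulated study group.

    ``plan.center_mm`` of None means "align the plan on the segmented
    target", which is the study's planning workflow; a mistarget plan then
    adds its lateral shift on top. ``correction_mm`` is the calibration
    correction built into the targeting (all zeros before refinement).
    """

    group: str
    seeds: List[int]
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    plan: TreatmentPlan = field(default_factory=lambda: TreatmentPlan(center_mm=None))
    calib: CalibrationState = field(default_factory=CalibrationState)
    cloud: BubbleCloudSpec = field(default_factory=BubbleCloudSpec)
    imaging: ImagingParams = field(default_factory=ImagingParams)
    seg: SegmentationParams = field(default_factory=SegmentationParams)
    mixing_window_mm: float = 5.0
    correction_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    randomize_layer_phase: bool = True
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def n_phantoms(self) -> int:
        return len(self.seeds)

    @classmethod
    def for_group(
        cls,
        group: str,
        seeds: Sequence[int],
        true_offset_mm: Optional[Tuple[float, float, float]] = None,
        **kwargs,
    ) -> "StudyConfig":
        """Build a config with the group's planning geometry defaults:
        28 mm centred (calibration groups), 20 mm centred (undertreatment),
        or 28 mm with a +7 mm Y shift (mistarget). The hidden calibration
        offset defaults to (0, 0, -2.4) mm for the pre-refinement group and
        zero otherwise."""
        if group in ("pre_refinement", "post_refinement"):
            plan = TreatmentPlan(center_mm=None, diameter_mm=28.0)
            default_offset = (0.0, 0.0, -2.4)
        elif group == "undertreatment":
            plan = TreatmentPlan(center_mm=None, diameter_mm=20.0)
            default_offset = (0.0, 0.0, 0.0)
        else:  # mistarget
            plan = TreatmentPlan(
                center_mm=None, diameter_mm=28.0, lateral_shift_mm=(0.0, 7.0, 0.0)
            )
            default_offset = (0.0, 0.0, 0.0)
        calib = CalibrationState(
            true_offset_mm=true_offset_mm if true_offset_mm is not None else default_offset
        )
        return cls(group=group, seeds=list(seeds), plan=plan, calib=calib, **kwargs)


@dataclass
class StudyReport:
    """Per-phantom measurements plus group-level statistics."""

    group: str
    table: pd.DataFrame
    stats: Optional[GroupStats] = None
    correction: Optional[CalibrationCorrection] = None

    def offsets(self) -> List[OffsetMeasurement]:
        ok = self.table[self.table["status"] == "ok"]
        return [
            OffsetMeasurement(r.dx_mm, r.dy_mm, r.dz_mm) for r in ok.itertuples()
        ]

    def to_json(self) -> str:
        payload = {
            "group": self.group,
            "rows": self.table.to_dict(orient="records"),
        }
        if self.stats is not None:
            payload["stats"] = {
                "n": self.stats.n,
                "mean_per_axis": list(self.stats.mean_per_axis),
                "sd_per_axis": list(self.stats.sd_per_axis),
                "mean_abs_per_axis": list(self.stats.mean_abs_per_axis),
                "sd_abs_per_axis": list(self.stats.sd_abs_per_axis),
                "mean_euclidean_mm": self.stats.mean_euclidean_mm,
                "sd_euclidean_mm": self.stats.sd_euclidean_mm,
            }
        if self.correction is not None:
            payload["correction_mm"] = list(self.correction.correction_mm)
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StudyReport":
        payload = json.loads(text)
        table = pd.DataFrame(payload["rows"], columns=_ROW_COLUMNS)
        stats = None
        if "stats" in payload:
            s = payload["stats"]
            stats = GroupStats(
                n=s["n"],
                mean_per_axis=np.array(s["mean_per_axis"]),
                sd_per_axis=np.array(s["sd_per_axis"]),
                mean_abs_per_axis=np.array(s["mean_abs_per_axis"]),
                sd_abs_per_axis=np.array(s["sd_abs_per_axis"]),
                mean_euclidean_mm=s["mean_euclidean_mm"],
                sd_euclidean_mm=s["sd_euclidean_mm"],
            )
        correction = None
        if "correction_mm" in payload:
            correction = CalibrationCorrection(np.array(payload["correction_mm"]))
        return cls(payload["group"], table, stats, correction)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _stage_seed(seed: int, stage: int) -> int:
    """Derived per-stage seed; stays below 2**31."""
    return int(np.random.SeedSequence((int(seed), stage)).generate_state(1)[0] % (2**31))


def default_layer_rois(
    spec: PhantomSpec, kind: str, n: int = 3, radius_mm: float = 3.0
) -> List[Roi]:
    """ROIs in ``n`` consecutive intact outer-phantom layers.

    ``kind`` is "barium" (high-attenuation) or "nonbarium". The disks lie
    in the axial plane (parallel to the layers) at each layer's centre
    depth, at an XY position in the phantom corner, clear of the target and
    of any centred treatment.
    """
    if kind not in ("barium", "nonbarium"):
        raise ValueError("kind must be 'barium' or 'nonbarium'")
    period = spec.layer_period_mm
    first = spec.outer_layer_phase_mm + (
        spec.low_layer_thickness_mm + spec.high_layer_thickness_mm / 2.0
        if kind == "barium"
        else spec.low_layer_thickness_mm / 2.0
    )
    dims = np.asarray(spec.outer_dims_mm, float)
    zc = dims[2] / 2.0
    ks = np.arange(-2, int(np.floor(dims[2] / period)) + 3)
    z_all = first + period * ks
    z_all = z_all[(z_all > 1.0) & (z_all < dims[2] - 1.0)]
    order = np.argsort(np.abs(z_all - zc))
    z_sel = np.sort(z_all[order[:n]])
    margin = radius_mm + 2.0
    xy = (dims[0] - margin, dims[1] - margin)
    return [Roi("axial", (xy[0], xy[1], z), radius_mm) for z in z_sel]


def _treatment_zone_rois(center_mm, radius_mm: float = 3.0) -> List[Roi]:
    c = tuple(np.asarray(center_mm, float))
    return [Roi(p, c, radius_mm) for p in ("axial", "coronal", "sagittal")]


def run_single_phantom(config: StudyConfig, seed: int) -> dict:
    """Run the full QA chain for one phantom; returns one report row."""
    spec = config.phantom
    if config.randomize_layer_phase:
        # hand-poured phantoms start their layer stack at an arbitrary
        # height; the target's phase mismatch is relative, so it is kept
        phase_rng = np.random.default_rng(_stage_seed(seed, 0))
        spec = replace(
            spec, outer_layer_phase_mm=float(phase_rng.uniform(0.0, spec.layer_period_mm))
        )
    truth, target_truth = build_phantom(spec)
    pre = simulate_cbct(
        truth, config.imaging.psf_sigma_mm, config.imaging.noise_sd, _stage_seed(seed, 1)
    )

    # operator-click surrogate: seed target segmentation at the phantom centre
    approx = np.asarray(spec.target_center_mm, float)
    target_mask = segment_target(pre, approx, config.seg)
    target_center = centroid(target_mask)

    plan_center = (
        target_center if config.plan.center_mm is None else np.asarray(config.plan.center_mm, float)
    )
    plan = replace(config.plan, center_mm=tuple(plan_center))
    path = plan_helical_path(plan, config.cloud)
    executed = path.translated(-np.asarray(config.correction_mm, float))
    post_truth, treated_truth = apply_treatment(
        truth,
        executed,
        config.calib,
        mixing_window_mm=config.mixing_window_mm,
        seed=_stage_seed(seed, 2),
    )
    post = simulate_cbct(
        post_truth, config.imaging.psf_sigma_mm, config.imaging.noise_sd, _stage_seed(seed, 3)
    )

    zone = segment_treatment_zone(pre, post, config.seg)
    offset = measure_offset(plan.effective_center_mm, zone)
    diam = measure_diameters(zone)
    tt = target_to_treatment_distance(target_mask, zone)

    noise_sd = noise_sd_from_layers(
        pre, RoiSet(default_layer_rois(spec, "barium") + default_layer_rois(spec, "nonbarium"))
    )
    es = edge_strength(pre, target_mask, EdgeStrengthConfig(), noise_sd)
    treat_rois = measure_rois(post, _treatment_zone_rois(centroid(zone)))
    ba_rois = measure_rois(post, default_layer_rois(spec, "barium"))
    nb_rois = measure_rois(post, default_layer_rois(spec, "nonbarium"))

    return {
        "seed": seed,
        "status": "ok",
        "dx_mm": offset.dx_mm,
        "dy_mm": offset.dy_mm,
        "dz_mm": offset.dz_mm,
        "euclidean_mm": offset.euclidean_mm,
        "diam_x_mm": diam.diam_x_mm,
        "diam_y_mm": diam.diam_y_mm,
        "diam_z_mm": diam.diam_z_mm,
        "tt_dx_mm": tt.dx_mm,
        "tt_dy_mm": tt.dy_mm,
        "tt_dz_mm": tt.dz_mm,
        "tt_euclidean_mm": tt.euclidean_mm,
        "sdnr_vs_barium": sdnr(treat_rois, ba_rois),
        "sdnr_vs_nonbarium": sdnr(treat_rois, nb_rois),
        "edge_strength": es,
        "noise_sd": noise_sd,
    }


def run_study(config: StudyConfig) -> StudyReport:
    """Run every phantom in the group and aggregate.

    Per-phantom failures are recorded in the row's ``status`` and the study
    continues; an empty seed list yields an empty report.
    """
    rows = []
    for i, seed in enumerate(config.seeds):
        row = {"phantom": f"{config.group}_{i + 1}", "seed": seed}
        try:
            row.update(run_single_phantom(config, seed))
        except Exception as exc:  # failure flagged, study continues
            row["status"] = f"failed: {exc}"
        rows.append(row)
    table = pd.DataFrame(rows, columns=_ROW_COLUMNS)

    stats = None
    correction = None
    ok = table[table["status"] == "ok"]
    if len(ok) >= 1:
        offsets = [OffsetMeasurement(r.dx_mm, r.dy_mm, r.dz_mm) for r in ok.itertuples()]
        stats = group_stats(offsets)
        if config.group == "pre_refinement":
            correction = refine_calibration(stats)
    report = StudyReport(config.group, table, stats, correction)
    if config.output_dir is not None:
        import pathlib

        out = pathlib.Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / f"{config.group}_report.csv")
        (out / f"{config.group}_report.json").write_text(report.to_json())
    return report


def closed_loop_refinement(
    cal_config: StudyConfig, test_config: StudyConfig
) -> Tuple[CalibrationCorrection, StudyReport]:
    """Derive the calibration correction from a pre-refinement study and
    apply it in the test study (the correction is built into the targeting,
    i.e. subtracted from every delivered cloud position)."""
    if cal_config.group != "pre_refinement":
        raise ValueError("calibration config must use group='pre_refinement'")
    cal_report = run_study(cal_config)
    if cal_report.correction is None:
        raise RuntimeError("calibration study produced no usable measurements")
    correction = cal_report.correction
    corrected = replace(
        test_config,
        correction_mm=tuple(
            np.asarray(test_config.correction_mm, float) + correction.correction_mm
        ),
    )
    return correction, run_study(corrected)
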