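"""Reading and writing volumes, masks and configurations.

Volumes and masks are exchanged as NRRD or MetaImage (``.mhd``/``.raw``)
through SimpleITK; masks are stored as 0/1 unsigned-char volumes with the
same geometry header. Configurations are flat JSON/YAML mappings of
dataclass fields.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import yaml

from .grid import BinaryMask, Volume
from .phantom import PhantomSpec
from .treatment import BubbleCloudSpec, CalibrationState, CloudPath, TreatmentPlan

__all__ = [
    "write_volume",
    "read_volume",
    "write_mask",
    "read_mask",
    "write_path_csv",
    "load_config",
    "save_config",
    "phantom_spec_from_mapping",
    "treatment_plan_from_mapping",
]


def _to_sitk(values: np.ndarray, spacing: float, origin: np.ndarray) -> sitk.Image:
    # SimpleITK arrays are indexed (z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing((spacing,) * 3)
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def write_volume(vol: Volume, path) -> None:
    """Write a volume as NRRD or MetaImage, chosen by file extension."""
    sitk.WriteImage(_to_sitk(vol.values.astype(np.float32), vol.spacing_mm, vol.origin_mm), str(path))


def read_volume(path) -> Volume:
    img = sitk.ReadImage(str(path))
    spacing = img.GetSpacing()
    if abs(spacing[0] - spacing[1]) > 1e-6 or abs(spacing[0] - spacing[2]) > 1e-6:
        raise ValueError(f"anisotropic spacing {spacing} not supported")
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return Volume(values.astype(float), float(spacing[0]), np.asarray(img.GetOrigin()))


def write_mask(mask: BinaryMask, path) -> None:
    sitk.WriteImage(
        _to_sitk(mask.values.astype(np.uint8), mask.spacing_mm, mask.origin_mm), str(path)
    )


def read_mask(path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.values > 0.5, vol.spacing_mm, vol.origin_mm)


def write_path_csv(path_obj: CloudPath, path) -> None:
    """Export cloud centres as a CSV of x_mm, y_mm, z_mm rows."""
    header = "x_mm,y_mm,z_mm"
    np.savetxt(str(path), path_obj.centers_mm, delimiter=",", header=header, comments="")


def save_config(obj, path) -> None:
    """Serialize a config dataclass as flat YAML or JSON (by extension)."""
    data = dataclasses.asdict(obj)

    def clean(v):
        if isinstance(v, np.ndarray):
            return [float(x) for x in v]
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    data = clean(data)
    p = Path(path)
    if p.suffix in (".yaml", ".yml"):
        p.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        p.write_text(json.dumps(data, indent=2))


def _load_mapping(path) -> dict:
    p = Path(path)
    text = p.read_text()
    if p.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def load_config(path) -> dict:
    """Load a JSON/YAML config file into a plain mapping."""
    return _load_mapping(path)


def _coerce(cls, mapping: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in mapping.items()
    }
    return cls(**kwargs)


def phantom_spec_from_mapping(mapping: dict) -> PhantomSpec:
    return _coerce(PhantomSpec, mapping)


def treatment_plan_from_mapping(mapping: dict) -> TreatmentPlan:
    return _coerce(TreatmentPlan, mapping)


def calibration_from_mapping(mapping: dict) -> CalibrationState:
    return _coerce(CalibrationState, mapping)


def cloud_from_mapping(mapping: dict) -> BubbleCloudSpec:
    return _coerce(BubbleCloudSpec, mapping)
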