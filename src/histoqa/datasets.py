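"""Bundled reference measurements.

``calibration_offsets.csv`` holds the per-phantom planned-vs-actual
treatment centroid offsets measured in the prototype CBCT-guided
histotripsy calibration study: six phantoms treated before calibration
refinement (group ``before_refinement``) and six after
(``after_refinement``). These published measurements serve as worked-example
inputs for the offset statistics and the refinement rule.
"""

from __future__ import annotations

from importlib import resources
from typing import List, Tuple

import pandas as pd

from .metrics import OffsetMeasurement

__all__ = ["load_reference_offsets", "reference_offset_groups"]


def load_reference_offsets() -> pd.DataFrame:
    """Per-phantom measured offsets (mm) with columns
    ``phantom, group, dx_mm, dy_mm, dz_mm``."""
    with resources.files(__package__).joinpath("data/calibration_offsets.csv").open() as fh:
        return pd.read_csv(fh)


def reference_offset_groups() -> Tuple[List[OffsetMeasurement], List[OffsetMeasurement]]:
    """The two measurement groups (before, after refinement) as
    :class:`OffsetMeasurement` lists."""
    df = load_reference_offsets()
    out = []
    for name in ("before_refinement", "after_refinement"):
        sub = df[df["group"] == name]
        out.append([OffsetMeasurement(r.dx_mm, r.dy_mm, r.dz_mm) for r in sub.itertuples()])
    return tuple(out)
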