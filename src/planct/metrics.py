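"""Quantitative evaluation of a synthesized CT against its target CT.

Per structure (body, lungs, GTV): RASSD (root averaged squared sum of
differences, the RMS intensity discrepancy in HU), Dice similarity
coefficient, and the exact symmetric Hausdorff distance between surface
voxel sets (mm, spacing-aware). Because scan lengths differ, the body
comparison is restricted to the z-slices where both body masks are nonempty.
Folding of the accompanying displacement field is reported as the fraction
of interior voxels with non-positive Jacobian determinant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .diffeo import folding_fraction
from .errors import DegenerateInputError, GridMismatchError
from .volumes import (
    BinaryMask,
    DisplacementField,
    ScalarVolume,
    VolumeGrid,
    overlapping_z_range,
)

__all__ = [
    "StructureMetrics",
    "CaseReport",
    "rassd",
    "dsc",
    "hausdorff",
    "evaluate_case",
    "cohort_summary",
]


def _check_grids(a, b):
    if not a.grid.matches(b.grid):
        raise GridMismatchError("operands must share a grid")


def rassd(a: ScalarVolume, b: ScalarVolume,
          region: BinaryMask | None = None) -> float:
    """Root mean squared voxelwise difference (HU) over the region."""
    _check_grids(a, b)
    diff = a.values - b.values
    if region is not None:
        _check_grids(a, region)
        if not region.values.any():
            raise DegenerateInputError("empty region for RASSD")
        diff = diff[region.values]
    return float(np.sqrt(np.mean(diff**2)))


def dsc(x: BinaryMask, y: BinaryMask) -> float:
    """Dice similarity coefficient 2|X∩Y|/(|X|+|Y|); both-empty -> 1."""
    _check_grids(x, y)
    nx, ny = x.voxel_count, y.voxel_count
    if nx + ny == 0:
        return 1.0
    inter = int((x.values & y.values).sum())
    return 2.0 * inter / (nx + ny)


def _surface_coordinates(mask: BinaryMask) -> np.ndarray:
    """Physical coordinates (mm) of foreground voxels with a 6-neighbor
    background (or volume-border) face."""
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask.values, structure=structure,
                                    border_value=0)
    surface = mask.values & ~eroded
    idx = np.argwhere(surface).astype(np.float64)
    return idx * np.asarray(mask.grid.spacing) + np.asarray(mask.grid.origin)


def hausdorff(x: BinaryMask, y: BinaryMask) -> float:
    """Exact symmetric Hausdorff distance (mm) between surface voxel sets."""
    _check_grids(x, y)
    if not x.values.any() or not y.values.any():
        raise DegenerateInputError("Hausdorff distance requires nonempty masks")
    pa, pb = _surface_coordinates(x), _surface_coordinates(y)
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


@dataclass
class StructureMetrics:
    rassd: float  # HU
    dsc: float  # unitless, [0, 1]
    hd: float  # mm


@dataclass
class CaseReport:
    structures: dict[str, StructureMetrics]
    folding_fraction: float
    z_range_used: tuple[int, int] | None

    def to_dict(self) -> dict:
        return {
            "structures": {
                k: {"rassd": v.rassd, "dsc": v.dsc, "hd": v.hd}
                for k, v in self.structures.items()
            },
            "folding_fraction": self.folding_fraction,
            "z_range_used": list(self.z_range_used)
            if self.z_range_used is not None else None,
        }


def _crop_z(obj, lo: int, hi: int):
    grid = obj.grid
    new_grid = VolumeGrid(
        (grid.shape[0], grid.shape[1], hi - lo + 1),
        grid.spacing,
        (grid.origin[0], grid.origin[1], grid.origin[2] + lo * grid.spacing[2]),
    )
    return type(obj)(new_grid, obj.values[:, :, lo:hi + 1])


def evaluate_case(
    sct: ScalarVolume,
    pct: ScalarVolume,
    masks_s: dict[str, BinaryMask],
    masks_p: dict[str, BinaryMask],
    dvf: DisplacementField,
) -> CaseReport:
    """Per-structure RASSD/DSC/HD plus folding for one case.

    The body structure is compared only on the overlapping z-range of the two
    body masks (RASSD over the whole cropped volume); other structures are
    compared on the full grid with RASSD restricted to the union of the two
    structure masks.
    """
    if set(masks_s) != set(masks_p):
        raise ValueError(
            f"structure sets differ: {sorted(masks_s)} vs {sorted(masks_p)}"
        )
    _check_grids(sct, pct)
    z_range = None
    out: dict[str, StructureMetrics] = {}
    for name in sorted(masks_s):
        ms, mp = masks_s[name], masks_p[name]
        if name == "body":
            z_range = overlapping_z_range(ms, mp)
            if z_range is None:
                raise DegenerateInputError("body masks share no z-slices")
            lo, hi = z_range
            sub_s, sub_p = _crop_z(sct, lo, hi), _crop_z(pct, lo, hi)
            ms_c, mp_c = _crop_z(ms, lo, hi), _crop_z(mp, lo, hi)
            out[name] = StructureMetrics(
                rassd=rassd(sub_s, sub_p),
                dsc=dsc(ms_c, mp_c),
                hd=hausdorff(ms_c, mp_c),
            )
        else:
            union = BinaryMask(ms.grid, ms.values | mp.values)
            out[name] = StructureMetrics(
                rassd=rassd(sct, pct, region=union),
                dsc=dsc(ms, mp),
                hd=hausdorff(ms, mp),
            )
    return CaseReport(
        structures=out,
        folding_fraction=folding_fraction(dvf),
        z_range_used=z_range,
    )


def cohort_summary(reports: list[CaseReport]) -> pd.DataFrame:
    """Mean/median/min/max per structure and metric across cases."""
    if not reports:
        raise ValueError("cohort_summary requires at least one report")
    rows = []
    for rep in reports:
        for name, m in rep.structures.items():
            rows.append({"structure": name, "rassd": m.rassd, "dsc": m.dsc,
                         "hd": m.hd, "folding_fraction": rep.folding_fraction})
    df = pd.DataFrame(rows)
    long = df.melt(id_vars="structure", var_name="metric", value_name="value")
    table = (
        long.groupby(["structure", "metric"])["value"]
        .agg(["mean", "median", "min", "max"])
        .reset_index()
    )
    return table
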