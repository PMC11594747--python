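"""Regional aggregation of the OCT posterior-pole superpixel grid.

Ganglion-cell-layer thickness is averaged over two region systems that
approximately overlap the multifocal stimulus topographies:

* three concentric areas — Area 1: 0-6.35 deg from the fovea, Area 2:
  6.35-9.37 deg, Area 3: 9.37-12.5 deg (superpixels assigned by the radial
  distance of their centre, half-open [inner, outer) intervals);
* four anatomical quadrant sectors (ST/SN/IN/IT) of 13 superpixels each:
  each quadrant's 16 superpixels minus the 3 closest to the fovea, which
  belong to the separately analysed central area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .geometry import Superpixel, assign_sector, build_posterior_pole_grid

# Area 2's outer bound; a source-data ambiguity between 9.31 and 9.37 is
# resolved to 9.37, consistent with Area 3's stated inner bound.
AREA_BOUNDS = {"Area1": (0.0, 6.35), "Area2": (6.35, 9.37), "Area3": (9.37, 12.5)}
AREA_LABELS = tuple(AREA_BOUNDS)
SECTOR_SIZE = 13  # superpixels per quadrant sector


@dataclass
class GclRegionalThickness:
    eye_id: str
    region: str          # Area1..Area3 or ST/IT/IN/SN
    value: float         # um
    n_superpixels: int


def map_superpixels_to_areas(grid: list[Superpixel]) -> dict[str, list[Superpixel]]:
    """Partition superpixels into the concentric areas by centre distance.

    Superpixels whose centre lies beyond 12.5 degrees are left unassigned.
    """
    out: dict[str, list[Superpixel]] = {a: [] for a in AREA_LABELS}
    for sp in grid:
        d = sp.center_distance
        for area, (lo, hi) in AREA_BOUNDS.items():
            if lo <= d < hi:
                out[area].append(sp)
                break
    return out


def map_superpixels_to_sectors(grid: list[Superpixel],
                               laterality: str = "OD") -> dict[str, list[Superpixel]]:
    """Split the grid into four 13-superpixel quadrant sectors.

    Each quadrant contributes its 16 superpixels minus the 3 nearest the
    fovea.  Distance ties are broken by (row, col) order.
    """
    quads: dict[str, list[Superpixel]] = {"ST": [], "SN": [], "IN": [], "IT": []}
    for sp in grid:
        quads[assign_sector(sp.center_x, sp.center_y, laterality)].append(sp)
    out = {}
    for sector, members in quads.items():
        members = sorted(members, key=lambda sp: (sp.center_distance, sp.row, sp.col))
        out[sector] = sorted(members[3:], key=lambda sp: (sp.row, sp.col))
    return out


def regional_thickness(assignment: dict[str, list[Superpixel]],
                       eye_id: str = "") -> list[GclRegionalThickness]:
    """Unweighted mean thickness over each region's member superpixels."""
    results = []
    for region, members in assignment.items():
        if not members:
            raise ValueError(f"region {region} has no superpixels")
        total = 0.0
        for sp in members:
            if sp.thickness is None:
                raise ValueError(
                    f"superpixel (row={sp.row}, col={sp.col}) in {region} "
                    "has no thickness value")
            total += sp.thickness
        results.append(GclRegionalThickness(
            eye_id=eye_id, region=region,
            value=total / len(members), n_superpixels=len(members)))
    return results


def grid_regional_means(grid: list[Superpixel], laterality: str = "OD",
                        eye_id: str = "") -> list[GclRegionalThickness]:
    """Thickness of all seven regions (3 areas + 4 sectors) of one grid."""
    areas = map_superpixels_to_areas(grid)
    sectors = map_superpixels_to_sectors(grid, laterality)
    return regional_thickness({**areas, **sectors}, eye_id=eye_id)


def load_thickness_grid(path) -> list[Superpixel]:
    """Read an 8x8 thickness grid from CSV (columns row, col, thickness_um)."""
    df = pd.read_csv(path, comment="#")
    required = {"row", "col", "thickness_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"grid CSV must have columns {sorted(required)}")
    grid = build_posterior_pole_grid()
    by_rc = {(int(r.row), int(r.col)): float(r.thickness_um)
             for r in df.itertuples()}
    for sp in grid:
        if (sp.row, sp.col) not in by_rc:
            raise ValueError(f"missing thickness for superpixel ({sp.row}, {sp.col})")
        sp.thickness = by_rc[(sp.row, sp.col)]
    return grid
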