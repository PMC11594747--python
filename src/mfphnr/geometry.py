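"""Stimulus and OCT grid geometry.

The multifocal stimulus is a dartboard of 60 scaled dart elements tiling the
central 20 degrees of the visual field, organised in four concentric rings
(R1: 0-5 deg, R2: 5-10, R3: 10-15, R4: 15-20).  The OCT posterior-pole
analysis grid is an 8x8 array of superpixels covering the central
30 x 25 degrees of the macula.

Coordinates are visual-space degrees with the fovea at the origin, in a
right-eye (OD) anatomical frame: temporal = negative x, superior = positive y.
Left eyes (OS) are handled by mirroring x before any sector lookup, so the
sector labels (ST/SN/IN/IT) are always anatomical, never screen-side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

RING_BOUNDARIES = (0.0, 5.0, 10.0, 15.0, 20.0)
RING_LABELS = ("R1", "R2", "R3", "R4")

# Wedges per ring: 12 + 12 + 18 + 18 = 60.  R1/R2 use 3 wedges per quadrant;
# R3/R4 cannot split 18 equally over 4 quadrants, so quadrants alternate
# 5 and 4 wedges.  All wedge boundaries fall on the meridians, so every
# element lies wholly inside one anatomical sector.
_WEDGES_PER_QUADRANT = {"R1": (3, 3, 3, 3), "R2": (3, 3, 3, 3),
                        "R3": (5, 4, 5, 4), "R4": (5, 4, 5, 4)}

SECTOR_LABELS = ("ST", "SN", "IN", "IT")

GRID_SHAPE = (8, 8)
GRID_WIDTH_DEG = 30.0
GRID_HEIGHT_DEG = 25.0
SUPERPIXEL_WIDTH = GRID_WIDTH_DEG / GRID_SHAPE[1]    # 3.75 deg
SUPERPIXEL_HEIGHT = GRID_HEIGHT_DEG / GRID_SHAPE[0]  # 3.125 deg


@dataclass(frozen=True)
class StimulusConfig:
    """Parameters of the multifocal pattern-reversal stimulus."""

    n_elements: int = 60
    max_ecc: float = 20.0
    background_luminance: float = 200.0  # cd/m^2
    on_luminance: float = 400.0          # cd/m^2
    off_luminance: float = 0.0           # cd/m^2
    stimulus_frequency: float = 7.0      # Hz
    mseq_order: int = 12                 # bits

    def __post_init__(self) -> None:
        for name in ("background_luminance", "on_luminance", "off_luminance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mseq_order < 2:
            raise ValueError("mseq_order must be >= 2")
        if self.max_ecc <= 0:
            raise ValueError("max_ecc must be positive")
        if self.stimulus_frequency <= 0:
            raise ValueError("stimulus_frequency must be positive")


@dataclass(frozen=True)
class StimulusElement:
    """One dart of the stimulus: an annulus sector in visual-space degrees."""

    element_id: int
    inner_ecc: float
    outer_ecc: float
    theta_start: float  # polar angle, degrees CCW from nasal horizontal (OD)
    theta_end: float
    area: float         # deg^2
    ring_label: str
    sector_label: str   # S1 for the central 5-deg disc, else quadrant label

    @property
    def centroid(self) -> tuple[float, float]:
        r = 0.5 * (self.inner_ecc + self.outer_ecc)
        th = math.radians(0.5 * (self.theta_start + self.theta_end))
        return (r * math.cos(th), r * math.sin(th))


def ring_label_for(inner_ecc: float, outer_ecc: float) -> str:
    """Ring label for an annulus [inner, outer) against the 5/10/15/20 bounds."""
    for i, lab in enumerate(RING_LABELS):
        lo, hi = RING_BOUNDARIES[i], RING_BOUNDARIES[i + 1]
        if abs(inner_ecc - lo) < 1e-9 and abs(outer_ecc - hi) < 1e-9:
            return lab
    raise ValueError(f"annulus [{inner_ecc}, {outer_ecc}) does not match ring bounds")


def assign_sector(x: float, y: float, laterality: str = "OD") -> str:
    """Anatomical quadrant of a point (degrees from fovea).

    OS coordinates are mirrored in x so that temporal is always negative x.
    Points on the vertical midline go to the temporal side, points on the
    horizontal midline to the superior side (deterministic tie-break).
    """
    if laterality not in ("OD", "OS"):
        raise ValueError("laterality must be 'OD' or 'OS'")
    if x == 0.0 and y == 0.0:
        raise ValueError("sector undefined at the fovea (0, 0)")
    if laterality == "OS":
        x = -x
    temporal = x <= 0.0
    superior = y >= 0.0
    if superior:
        return "ST" if temporal else "SN"
    return "IT" if temporal else "IN"


def _annulus_sector_area(r_in: float, r_out: float, dtheta_deg: float) -> float:
    return (dtheta_deg / 360.0) * math.pi * (r_out**2 - r_in**2)


def build_dartboard(config: Optional[StimulusConfig] = None) -> list[StimulusElement]:
    """Build the 60-element scaled-dart tessellation of the 20-degree disc.

    Elements are ordered ring by ring from the centre, counter-clockwise
    starting at the nasal horizontal meridian (OD frame).
    """
    config = config or StimulusConfig()
    elements: list[StimulusElement] = []
    eid = 0
    for ri, ring in enumerate(RING_LABELS):
        r_in, r_out = RING_BOUNDARIES[ri], RING_BOUNDARIES[ri + 1]
        for q in range(4):  # quadrants in theta order: SN, ST, IT, IN
            q_start = 90.0 * q
            n_w = _WEDGES_PER_QUADRANT[ring][q]
            width = 90.0 / n_w
            for w in range(n_w):
                th0 = q_start + w * width
                th1 = th0 + width
                area = _annulus_sector_area(r_in, r_out, width)
                if r_out <= 5.0:
                    sector = "S1"
                else:
                    thm = math.radians(0.5 * (th0 + th1))
                    rm = 0.5 * (r_in + r_out)
                    sector = assign_sector(rm * math.cos(thm), rm * math.sin(thm), "OD")
                elements.append(StimulusElement(
                    element_id=eid, inner_ecc=r_in, outer_ecc=r_out,
                    theta_start=th0, theta_end=th1, area=area,
                    ring_label=ring, sector_label=sector))
                eid += 1
    assert len(elements) == config.n_elements
    return elements


@dataclass
class Superpixel:
    """One cell of the OCT posterior-pole analysis grid."""

    row: int
    col: int
    center_x: float  # degrees from fovea, OD frame (temporal negative)
    center_y: float  # degrees from fovea, superior positive
    width: float = SUPERPIXEL_WIDTH
    height: float = SUPERPIXEL_HEIGHT
    thickness: Optional[float] = None  # um, populated by OCT or simulation

    @property
    def center_distance(self) -> float:
        return math.hypot(self.center_x, self.center_y)


def build_posterior_pole_grid() -> list[Superpixel]:
    """The 8x8 superpixel grid covering 30 x 25 degrees, fovea-centred.

    Row 0 is the most superior row; column 0 the most temporal (OD frame).
    """
    grid = []
    for row in range(GRID_SHAPE[0]):
        for col in range(GRID_SHAPE[1]):
            cx = (col - (GRID_SHAPE[1] - 1) / 2.0) * SUPERPIXEL_WIDTH
            cy = ((GRID_SHAPE[0] - 1) / 2.0 - row) * SUPERPIXEL_HEIGHT
            grid.append(Superpixel(row=row, col=col, center_x=cx, center_y=cy))
    return grid


def elements_to_frame(elements: list[StimulusElement]) -> pd.DataFrame:
    return pd.DataFrame([{
        "element_id": e.element_id, "inner_ecc": e.inner_ecc,
        "outer_ecc": e.outer_ecc, "theta_start": e.theta_start,
        "theta_end": e.theta_end, "area_deg2": e.area,
        "ring": e.ring_label, "sector": e.sector_label} for e in elements])


def superpixels_to_frame(grid: list[Superpixel], laterality: str = "OD") -> pd.DataFrame:
    return pd.DataFrame([{
        "row": sp.row, "col": sp.col, "center_x": sp.center_x,
        "center_y": sp.center_y,
        "sector": assign_sector(sp.center_x, sp.center_y, laterality),
        "thickness_um": sp.thickness} for sp in grid])


def total_stimulus_area(elements: list[StimulusElement]) -> float:
    return float(np.sum([e.area for e in elements]))
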