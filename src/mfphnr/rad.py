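"""The response-amplitude-density (RAD) statistic and regional aggregation.

RAD is the baseline-to-trough amplitude of one element's kernel divided by
the element's stimulated area (nV/deg^2): the pre-stimulus baseline mean
minus the most negative point of the trough sought between 50 and 90 ms
after stimulus onset.

Regional values follow the published aggregation rules: within a ring the
member elements are combined area-weighted (total amplitude over total
area); combinations across rings — R3+R4, and each quadrant sector as the
average of its R2, R3 and R4 portions — are unweighted means of the
already-averaged ring(-portion) densities.  S1 equals R1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import RING_LABELS, SECTOR_LABELS, StimulusElement
from .kernel import KernelSet
from .simulate import TROUGH_WINDOW_MS

BASELINE_WINDOW_MS = (-10.0, 0.0)


@dataclass
class RegionalMeasure:
    """One eye's value for one region: the atom of the cohort table."""

    eye_id: str
    region_type: str  # ring | area | sector
    region: str
    measure: str      # mfPhNR_RAD | GCL_T
    value: float
    units: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("regional value must be finite")


def measure_rad(kernel: np.ndarray, times_ms: np.ndarray, area: float,
                baseline_window: tuple[float, float] = BASELINE_WINDOW_MS,
                trough_window: tuple[float, float] = TROUGH_WINDOW_MS
                ) -> tuple[float, float]:
    """Baseline-to-trough amplitude density of one kernel.

    Returns ``(rad, trough_time_ms)``.  RAD is positive when the trough lies
    below the baseline; ties in the trough minimum resolve to the earliest
    time.  Raises if either window is not covered by the kernel.
    """
    times_ms = np.asarray(times_ms)
    for name, (lo, hi) in (("baseline", baseline_window), ("trough", trough_window)):
        if lo < times_ms[0] or hi > times_ms[-1]:
            raise ValueError(f"{name} window [{lo}, {hi}] ms outside kernel support")
    base = kernel[(times_ms >= baseline_window[0]) & (times_ms <= baseline_window[1])]
    in_trough = (times_ms >= trough_window[0]) & (times_ms <= trough_window[1])
    trough_vals = kernel[in_trough]
    i_min = int(np.argmin(trough_vals))  # argmin takes the earliest tie
    rad = (float(np.mean(base)) - float(trough_vals[i_min])) / area
    trough_time = float(times_ms[in_trough][i_min])
    return rad, trough_time


def element_rads(kernel_set: KernelSet, elements: Sequence[StimulusElement],
                 baseline_window: tuple[float, float] = BASELINE_WINDOW_MS,
                 trough_window: tuple[float, float] = TROUGH_WINDOW_MS
                 ) -> dict[int, float]:
    """RAD of every element in a kernel set."""
    by_id = {e.element_id: e for e in elements}
    out = {}
    for eid, k in kernel_set.kernels.items():
        rad, _ = measure_rad(k, kernel_set.times_ms, by_id[eid].area,
                             baseline_window, trough_window)
        out[eid] = rad
    return out


def _pooled_density(rads: dict[int, float], members: list[StimulusElement],
                    weighted: bool) -> float:
    if not members:
        raise ValueError("empty element group")
    members = sorted(members, key=lambda e: e.element_id)  # order-stable sums
    vals = np.array([rads[e.element_id] for e in members])
    if not weighted:
        return float(vals.mean())
    areas = np.array([e.area for e in members])
    return float((vals * areas).sum() / areas.sum())


def aggregate_rings(rads: dict[int, float], elements: Sequence[StimulusElement],
                    weighted: bool = True) -> dict[str, float]:
    """Ring densities R1..R4 plus the cross-ring average R3+R4."""
    out = {}
    for ring in RING_LABELS:
        members = [e for e in elements if e.ring_label == ring]
        if not members:
            raise ValueError(f"ring {ring} has no elements")
        out[ring] = _pooled_density(rads, members, weighted)
    out["R3+R4"] = 0.5 * (out["R3"] + out["R4"])
    return out


def aggregate_sectors(rads: dict[int, float], elements: Sequence[StimulusElement],
                      weighted: bool = True) -> dict[str, float]:
    """Sector densities: S1 (= R1) and the four quadrants of the 5-20 deg annulus.

    Each quadrant value is the unweighted mean of its R2, R3 and R4 portion
    densities, each portion combined area-weighted internally.
    """
    rings = aggregate_rings(rads, elements, weighted)
    out = {"S1": rings["R1"]}
    for sector in SECTOR_LABELS:
        portions = []
        for ring in ("R2", "R3", "R4"):
            members = [e for e in elements
                       if e.ring_label == ring and e.sector_label == sector]
            if not members:
                raise ValueError(f"sector {sector} has no {ring} elements")
            portions.append(_pooled_density(rads, members, weighted))
        out[sector] = float(np.mean(portions))
    return out


def eye_regional_measures(kernel_set: KernelSet,
                          elements: Sequence[StimulusElement],
                          weighted: bool = True,
                          group: str = "patient") -> list[RegionalMeasure]:
    """All regional RAD measures of one eye in cohort-table form."""
    rads = element_rads(kernel_set, elements)
    rings = aggregate_rings(rads, elements, weighted)
    sectors = aggregate_sectors(rads, elements, weighted)
    out = []
    for region in ("R1", "R2", "R3+R4"):
        out.append(RegionalMeasure(kernel_set.eye_id, "ring", region,
                                   "mfPhNR_RAD", rings[region], "nV_per_deg2"))
    for region in SECTOR_LABELS:
        out.append(RegionalMeasure(kernel_set.eye_id, "sector", region,
                                   "mfPhNR_RAD", sectors[region], "nV_per_deg2"))
    return out
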