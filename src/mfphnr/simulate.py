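"""Synthetic data generation for every stage of the pipeline.

No raw recordings are publicly deposited for this kind of study, so the
package ships a generator for each measured quantity:

* maximum-length (m-) sequences driving the pattern reversals;
* per-element response templates with a positive P1 peak and the negative
  PhNR trough at 50-90 ms after stimulus onset;
* multi-element trace sets (template superposition + white Gaussian noise);
* posterior-pole thickness grids hitting prescribed regional means;
* whole case-control cohorts with a prescribed structure-function
  correlation per region, defaulting to the bundled reference moments.

All randomness flows through an explicit seed per call.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.signal import max_len_seq

from .geometry import StimulusElement, Superpixel, build_dartboard, build_posterior_pole_grid
from .octgrid import map_superpixels_to_areas, map_superpixels_to_sectors
from .reference import REGION_PAIRS, load_reference_regressions, load_reference_summaries

TROUGH_WINDOW_MS = (50.0, 90.0)  # implicit-time window of the PhNR trough


def generate_mseq(order: int, seed_state: Optional[Sequence[int]] = None) -> np.ndarray:
    """Maximum-length sequence of length 2**order - 1 in +/-1 coding.

    ``seed_state`` is the initial shift-register state (``order`` bits, not
    all zero); the default is all ones.  The returned sequence is balanced
    up to one element and has periodic autocorrelation -1 at every nonzero
    lag (un-normalised, +/-1 coding).
    """
    if order < 2:
        raise ValueError("m-sequence order must be >= 2")
    state = None
    if seed_state is not None:
        state = np.asarray(seed_state, dtype=np.int8)
        if state.size != order:
            raise ValueError(f"seed_state must have {order} bits")
        if not state.any():
            raise ValueError("seed_state must not be all zeros")
    bits, _ = max_len_seq(order, state=state)
    return bits.astype(np.int8) * 2 - 1


@dataclass(frozen=True)
class WaveformParams:
    """Shape of one element's response template.

    Amplitudes are densities (nV/deg^2); the template itself is scaled by
    the element's area so its absolute trough depth is ``trough_amp * area``
    nV while the measured density stays at the nominal value.
    """

    p1_time: float = 35.0        # ms, positive peak
    p1_amp: float = 40.0         # nV/deg^2 (positive)
    trough_time: float = 70.0    # ms, within the 50-90 ms window
    trough_amp: float = 25.0     # nV/deg^2, stored as magnitude
    component_width: float = 5.0  # ms, Gaussian sigma of each component
    sampling_rate: float = 1000.0  # Hz

    def __post_init__(self) -> None:
        if not (TROUGH_WINDOW_MS[0] <= self.trough_time <= TROUGH_WINDOW_MS[1]):
            raise ValueError(f"trough_time must lie in {TROUGH_WINDOW_MS} ms")
        if self.trough_amp < 0:
            raise ValueError("trough_amp is a magnitude and must be >= 0")
        if self.p1_amp < 0:
            raise ValueError("p1_amp must be >= 0")
        if self.sampling_rate < 250:
            raise ValueError("sampling_rate must be >= 250 Hz")
        if self.component_width <= 0:
            raise ValueError("component_width must be positive")


def element_response_template(params: WaveformParams, area: float,
                              duration_ms: float = 120.0) -> np.ndarray:
    """Template response of one element over [0, duration_ms): P1 bump
    followed by the PhNR trough, both Gaussian, scaled by element area."""
    if duration_ms < 100.0:
        raise ValueError("epoch must be at least 100 ms to cover the trough window")
    if area <= 0:
        raise ValueError("element area must be positive")
    n = int(round(duration_ms * params.sampling_rate / 1000.0))
    t = np.arange(n) * 1000.0 / params.sampling_rate  # ms
    w = params.component_width
    bump = lambda t0: np.exp(-0.5 * ((t - t0) / w) ** 2)
    return area * (params.p1_amp * bump(params.p1_time)
                   - params.trough_amp * bump(params.trough_time))


@dataclass
class TraceSet:
    """Per-element recorded traces with their stimulus state sequences.

    Each element's trace is the superposition of state-signed template
    responses at every m-sequence step, plus noise.  All traces share the
    time axis; the recording starts ``pre_samples`` before the first step
    so epochs can carry a pre-stimulus baseline.
    """

    eye_id: str
    traces: dict[int, np.ndarray]          # element_id -> nV samples
    states: dict[int, np.ndarray]          # element_id -> +/-1 per step
    sampling_rate: float
    step_samples: int
    pre_samples: int
    epoch_ms: float

    @property
    def n_steps(self) -> int:
        return len(next(iter(self.states.values())))

    @property
    def onsets(self) -> np.ndarray:
        return self.pre_samples + np.arange(self.n_steps) * self.step_samples

    def validate(self) -> None:
        lengths = {len(s) for s in self.states.values()}
        if len(lengths) != 1:
            raise ValueError("all state sequences must have equal length")
        tlen = {len(t) for t in self.traces.values()}
        if len(tlen) != 1:
            raise ValueError("all traces must share the time axis")


def simulate_trace_set(elements: Sequence[StimulusElement],
                       mseq: np.ndarray,
                       params: Union[WaveformParams, dict[int, WaveformParams]],
                       noise_sd: float = 0.0,
                       seed: Optional[int] = None,
                       stimulus_frequency: float = 7.0,
                       pre_ms: float = 20.0,
                       epoch_ms: float = 120.0,
                       eye_id: str = "sim") -> TraceSet:
    """Simulate one eye's multifocal recording.

    Every element follows its own lag-shifted copy of the base m-sequence.
    At each step the element contributes its template multiplied by the
    stimulus state (+1/-1); white Gaussian noise of SD ``noise_sd`` (nV) is
    added to each trace.  Deterministic under a fixed seed.
    """
    if isinstance(params, WaveformParams):
        params = {e.element_id: params for e in elements}
    fs = next(iter(params.values())).sampling_rate
    step = int(round(fs / stimulus_frequency))
    pre = int(round(pre_ms * fs / 1000.0))
    if epoch_ms + pre_ms > step * 1000.0 / fs:
        raise ValueError("epoch (incl. pre-stimulus margin) longer than a stimulus step")
    n_steps = len(mseq)
    total = pre + n_steps * step
    shift = max(1, n_steps // max(len(elements), 1))
    rng = np.random.default_rng(seed)
    traces, states = {}, {}
    for i, el in enumerate(elements):
        s = np.roll(np.asarray(mseq, dtype=np.int8), -i * shift)
        template = element_response_template(params[el.element_id], el.area, epoch_ms)
        # one template per step; it fits within the step, so the epochs can
        # be laid out as rows of a (n_steps, step) block and the placement
        # is exact (no convolution round-off)
        padded = np.zeros(step)
        padded[:len(template)] = template
        block = s[:, None].astype(float) * padded[None, :]
        trace = np.concatenate([np.zeros(pre), block.ravel()])
        if noise_sd > 0:
            trace = trace + rng.normal(0.0, noise_sd, total)
        traces[el.element_id] = trace
        states[el.element_id] = s
    ts = TraceSet(eye_id=eye_id, traces=traces, states=states, sampling_rate=fs,
                  step_samples=step, pre_samples=pre, epoch_ms=epoch_ms)
    ts.validate()
    return ts


def save_trace_set(ts: TraceSet, csv_path, json_path) -> None:
    """Write a trace set as a wide samples CSV plus a JSON sidecar."""
    ids = sorted(ts.traces)
    df = pd.DataFrame({str(i): ts.traces[i] for i in ids})
    df.insert(0, "time_ms", np.arange(len(df)) * 1000.0 / ts.sampling_rate)
    df.to_csv(csv_path, index=False)
    sidecar = {
        "eye_id": ts.eye_id, "sampling_rate": ts.sampling_rate,
        "step_samples": ts.step_samples, "pre_samples": ts.pre_samples,
        "epoch_ms": ts.epoch_ms,
        "states": {str(i): ts.states[i].tolist() for i in ids},
    }
    with open(json_path, "w") as f:
        json.dump(sidecar, f)


def load_trace_set(csv_path, json_path) -> TraceSet:
    df = pd.read_csv(csv_path)
    with open(json_path) as f:
        sc = json.load(f)
    traces = {int(c): df[c].to_numpy() for c in df.columns if c != "time_ms"}
    states = {int(k): np.asarray(v, dtype=np.int8) for k, v in sc["states"].items()}
    ts = TraceSet(eye_id=sc["eye_id"], traces=traces, states=states,
                  sampling_rate=sc["sampling_rate"], step_samples=sc["step_samples"],
                  pre_samples=sc["pre_samples"], epoch_ms=sc["epoch_ms"])
    ts.validate()
    return ts


@dataclass(frozen=True)
class RegionPairMoments:
    """Group moments and target correlation for one RAD/GCL region pair."""

    rad_control_mean: float
    rad_control_sd: float
    rad_patient_mean: float
    rad_patient_sd: float
    gcl_control_mean: float
    gcl_control_sd: float
    gcl_patient_mean: float
    gcl_patient_sd: float
    r: float  # target structure-function correlation

    def __post_init__(self) -> None:
        for name in ("rad_control_sd", "rad_patient_sd",
                     "gcl_control_sd", "gcl_patient_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.r) > 1:
            raise ValueError("|r| <= 1 required (correlation matrix must be PSD)")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a simulated case-control cohort."""

    n_controls: int = 20
    n_patients: int = 21
    moments: dict[tuple, RegionPairMoments] = field(default_factory=lambda: default_moments())
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_controls < 2 or self.n_patients < 2:
            raise ValueError("need at least 2 eyes per group")


def default_moments() -> dict[tuple, RegionPairMoments]:
    """Reference moments: group summaries plus r = sqrt(published R^2)."""
    summ = load_reference_summaries().set_index(
        ["group", "region_type", "region", "measure"])
    regr = load_reference_regressions().set_index(
        ["rad_region_type", "rad_region"])
    out = {}
    for rad_key, gcl_key in REGION_PAIRS:
        def m(group, key, measure, col):
            return float(summ.loc[(group, key[0], key[1], measure), col])
        r2 = float(regr.loc[rad_key, "r2"])
        out[(rad_key, gcl_key)] = RegionPairMoments(
            rad_control_mean=m("control", rad_key, "mfPhNR_RAD", "mean"),
            rad_control_sd=m("control", rad_key, "mfPhNR_RAD", "sd"),
            rad_patient_mean=m("patient", rad_key, "mfPhNR_RAD", "mean"),
            rad_patient_sd=m("patient", rad_key, "mfPhNR_RAD", "sd"),
            gcl_control_mean=m("control", gcl_key, "GCL_T", "mean"),
            gcl_control_sd=m("control", gcl_key, "GCL_T", "sd"),
            gcl_patient_mean=m("patient", gcl_key, "GCL_T", "mean"),
            gcl_patient_sd=m("patient", gcl_key, "GCL_T", "sd"),
            r=math.sqrt(r2))
    return out


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a tidy cohort table from per-region bivariate normals.

    For each region pair and each eye, (RAD, GCL-T) are sampled jointly with
    the group's means/SDs and the pair's target correlation (applied in both
    groups).  Regions are drawn independently of each other.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    groups = [("control", "C", spec.n_controls), ("patient", "P", spec.n_patients)]
    for (rad_key, gcl_key), mom in spec.moments.items():
        for group, prefix, n in groups:
            if group == "control":
                mr, sr = mom.rad_control_mean, mom.rad_control_sd
                mg, sg = mom.gcl_control_mean, mom.gcl_control_sd
            else:
                mr, sr = mom.rad_patient_mean, mom.rad_patient_sd
                mg, sg = mom.gcl_patient_mean, mom.gcl_patient_sd
            z1 = rng.standard_normal(n)
            z2 = rng.standard_normal(n)
            rad = mr + sr * z1
            gcl = mg + sg * (mom.r * z1 + math.sqrt(1.0 - mom.r**2) * z2)
            for i in range(n):
                eye = f"{prefix}{i + 1:02d}"
                rows.append(dict(eye_id=eye, group=group, region_type=rad_key[0],
                                 region=rad_key[1], measure="mfPhNR_RAD",
                                 value=rad[i], units="nV_per_deg2"))
                rows.append(dict(eye_id=eye, group=group, region_type=gcl_key[0],
                                 region=gcl_key[1], measure="GCL_T",
                                 value=gcl[i], units="um"))
    return pd.DataFrame(rows)


def simulate_gcl_grid(sector_means: Optional[dict[str, float]] = None,
                      area_means: Optional[dict[str, float]] = None,
                      noise_sd: float = 0.0,
                      seed: Optional[int] = None,
                      laterality: str = "OD") -> list[Superpixel]:
    """Populate a posterior-pole grid whose regional means hit the targets.

    Thicknesses solve the regional-mean constraints exactly (minimum-norm
    least squares around the grand target mean), so noise-free regional
    averages equal the targets; with noise they do so in expectation.
    """
    if not sector_means and not area_means:
        raise ValueError("provide sector_means and/or area_means")
    for targets in (sector_means, area_means):
        if targets and any(v <= 0 for v in targets.values()):
            raise ValueError("target thicknesses must be positive")
    grid = build_posterior_pole_grid()
    index = {(sp.row, sp.col): i for i, sp in enumerate(grid)}
    regions: list[tuple[list[Superpixel], float]] = []
    if area_means:
        areas = map_superpixels_to_areas(grid)
        regions += [(areas[a], v) for a, v in area_means.items()]
    if sector_means:
        sectors = map_superpixels_to_sectors(grid, laterality)
        regions += [(sectors[s], v) for s, v in sector_means.items()]
    A = np.zeros((len(regions), len(grid)))
    b = np.zeros(len(regions))
    for k, (members, target) in enumerate(regions):
        for sp in members:
            A[k, index[(sp.row, sp.col)]] = 1.0 / len(members)
        b[k] = target
    m0 = float(np.mean([t for _, t in regions]))
    z, *_ = np.linalg.lstsq(A, b - A @ np.full(len(grid), m0), rcond=None)
    values = m0 + z
    if noise_sd > 0:
        values = values + np.random.default_rng(seed).normal(0, noise_sd, len(grid))
    for sp, v in zip(grid, values):
        sp.thickness = float(v)
    return grid
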