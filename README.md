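# mfphnr

Macular structure–function analysis for inner-retina disease: extraction of
the **multifocal photopic negative response (mfPhNR)** from m-sequence
multifocal ERG recordings, matched **OCT ganglion-cell-layer (GCL)**
thickness mapping on the posterior-pole superpixel grid, normative-limit
abnormality classification, and the case–control statistics that tie
function to structure in open-angle glaucoma (OAG).

The package is aimed at visual-electrophysiology and glaucoma researchers
who want a transparent, tested reference implementation of this analysis
chain — every stage is also exercisable on synthetic data, so no recordings
are required.

## The method

**Functional side.** A dartboard of 60 scaled dart elements tiles the
central 20° of the visual field (rings R1: 0–5°, R2: 5–10°, R3: 10–15°,
R4: 15–20°). Each element reverses between black and white following a
maximum-length binary sequence (m-sequence, length 2ᵏ−1), so the
**first-order kernel** of element *e* — its localized retinal response — is

> K_e = ½ · ( mean epoch | state_e = +1  −  mean epoch | state_e = −1 )

The **response amplitude density** (RAD, nV/deg²) of a kernel is the
pre-stimulus baseline mean minus the most negative point of the trough with
implicit time between 50 and 90 ms after stimulus onset, divided by the
element's area. Ring RADs combine member elements area-weighted; R3+R4 and
the quadrant sectors (ST/SN/IN/IT, each the mean of its R2/R3/R4 portions)
average the already-pooled densities.

**Structural side.** GCL thickness on the 8×8 posterior-pole grid
(30°×25°) is averaged over three concentric areas (0–6.35°, 6.35–9.37°,
9.37–12.5° from the fovea) and over four 13-superpixel quadrant sectors —
regions that approximately overlap the stimulus topographies.

**Statistics.** Group means/SDs; two-group one-way ANOVA (raw or from
summary statistics, F = n₁n₂/(n₁+n₂) · (m₁−m₂)² / s²_pooled); one-sided
lower 95 % normative limits from controls (mean − t₀.₉₇₅,ₙ₋₁·SD/√n, or
supplied published limits) with strict below-limit classification; OLS
regressions of RAD on GCL-T with t-based CIs and R²; and eccentricity/sector
trend fits with a group interaction term.

A bundled reference cohort (21 OAG eyes, 7 regions × 2 measures per eye,
plus published control summaries and normative limits) makes the whole
analysis reproducible from the repository alone.

## Worked example

```sh
python examples/reference_cohort_analysis.py
```

prints (abridged):

```
region  measure      patient_mean   F      %abnormal
R1      mfPhNR_RAD       15.924    84.48    100.0
Area1   GCL_T            26.829   128.22    100.0
Area3   GCL_T            20.190    53.22     95.2
SN      GCL_T            24.067    22.03     71.4

structure-function regressions (RAD on GCL-T, patients):
  R1     slope 0.75 [0.58, 0.93]  R2 0.81 p <0.001
  ST     slope 0.10 [0.06, 0.14]  R2 0.54 p <0.001

GCL-T thinning per area step: patients -3.32 um, controls -10.60 um
reconciliation, means match published: True
```

Reading the numbers: every patient regional mean reproduces the published
summary to 3 dp; ANOVA separates patients from controls decisively in every
region (all p < 0.001); all 21 eyes are functionally abnormal in every
region, while structural abnormality is incomplete peripherally (95.2 % in
Area 3, 71.4 % in the SN sector); function and structure are linearly
coupled, strongest centrally (R² ≈ 0.8); and GCL thinning with eccentricity
is much flatter in patients (−3.32 vs −10.60 µm per area step) because the
central area is already maximally reduced.

The other examples round-trip the signal chain
(`simulate_extract_measure.py`: a noise-free simulated recording yields
kernels equal to the generating templates and exactly the generating
25 nV/deg² in every region) and probe cohort-simulator parameter recovery
(`synthetic_cohort_recovery.py`).

## Layout

- `src/mfphnr/geometry.py` — stimulus dartboard, posterior-pole grid, sector conventions
- `src/mfphnr/simulate.py` — m-sequences, waveform templates, trace sets, grids, cohorts
- `src/mfphnr/kernel.py` — band-pass, artifact rejection, first-order kernels
- `src/mfphnr/rad.py` — the RAD statistic and ring/sector aggregation
- `src/mfphnr/octgrid.py` — OCT area/sector mapping and thickness averaging
- `src/mfphnr/stats.py` — ANOVA, normative limits, regressions, trends
- `src/mfphnr/io.py` — cohort table I/O and the end-to-end analysis
- `src/mfphnr/data/` — bundled reference cohort fixtures (CSV)
- `docs/methods.md` — model assumptions, parameter choices, limitations
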