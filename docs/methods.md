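# Methods

This note documents the models, conventions and numerical choices behind the
package, what the synthetic-data layer does and does not emulate, and the
known limitations.

## Stimulus geometry

The multifocal stimulus is modelled as 60 scaled dart elements tiling the
central 20° disc in four annuli (boundaries 0/5/10/15/20°). The precise
dart tessellation used by commercial systems is not public, so any
60-element tiling honouring the annuli is admissible; we use 12 wedges in
R1 and R2 and 18 in R3 and R4. Eighteen wedges cannot be split equally over
four quadrants, so R3/R4 quadrants alternate 5 and 4 wedges (22.5° and 18°
angular widths). All wedge boundaries lie on the horizontal/vertical
meridians, so every element belongs wholly to one anatomical sector and
sector aggregation is exact. Element areas are analytic annulus-sector
areas; the tiling is verified against an independent polygon oracle in the
tests.

Coordinates are visual-space degrees, fovea at the origin, in a right-eye
anatomical frame (temporal = negative x, superior = positive y). Left eyes
are mirrored in x before any sector lookup, so ST/SN/IN/IT labels are always
anatomical. Points exactly on the vertical midline are assigned to the
temporal side, on the horizontal midline to the superior side — a
deterministic tie-break that no element centroid or superpixel centre
actually hits.

Stimulus parameters (defaults): 200 cd/m² background, 0/400 cd/m² reversal
luminances, 7 Hz stimulus rate, 12-bit m-sequence. They are carried as
configuration; no display rendering is attempted.

## OCT posterior-pole grid

The grid is 8×8 superpixels covering 30°×25° (3.75°×3.125° each), centred
on the fovea; the device's exact pitch is not published, so the field of
view fixes the cell size. Concentric areas use the superpixel centre's
radial distance with half-open [inner, outer) boundaries: Area 1 0–6.35°,
Area 2 6.35–9.37°, Area 3 9.37–12.5° (a 9.31/9.37 ambiguity in the source
material is resolved to 9.37, consistent with Area 3's inner bound).
Centres beyond 12.5° are unassigned. Quadrant sectors take each quadrant's
16 superpixels minus the 3 nearest the fovea — which identity of the 13
retained superpixels is the only choice consistent with the central region
being analysed separately — leaving 4 disjoint sets of 13. Regional
thickness is the unweighted mean of member superpixels.

## Signal model and kernel extraction

Each element's response to one reversal is a template: a positive Gaussian
bump (P1) at 35 ms plus a negative Gaussian bump (the PhNR trough) at
70 ms, both with 5 ms sigma, scaled by element area so the density
amplitudes are area-free. The trough time is constrained to the 50–90 ms
implicit-time window. The defaults (P1 40 nV/deg², trough 25 nV/deg²)
produce healthy-eye central densities of the observed order.

A recording is simulated per element: stimulus steps of 1/7 s (one per
m-sequence element; steps treated as non-overlapping epochs), each step
contributing the template multiplied by the element's ±1 state, plus white
Gaussian noise. Each element follows its own lag-shifted copy of the base
m-sequence. Epochs carry a 20 ms pre-stimulus margin for the baseline and
extend 120 ms past onset, which fits within the 142.9 ms step, so epochs
never overlap and noise-free extraction is exact. m-sequences come from a
standard maximal-LFSR generator; balance and the −1 periodic
autocorrelation are property-tested against a brute-force oracle.

The first-order kernel is half the difference between the mean epoch under
the +1 state and under the −1 state. The production path computes it in one
pass from Σ E and Σ s·E (a DC-corrected cross-correlation, exact for the
m-sequence's one-step state imbalance); tests verify it against an explicit
epoch-partition oracle to 1e-9. Elements sharing an identical state
sequence are non-identifiable and flagged in QC. Cross-element kernel
contamination (deconvolution between simultaneously modulated elements) is
out of scope: traces are per-element, matching the per-element derived
traces a clinical system exports.

Preprocessing follows the clinical chain: an 8th-order Butterworth 3–100 Hz
band-pass applied forward–backward (zero phase, SOS), verified by FFT of
the impulse response (DC < −40 dB, <1 dB ripple over 6–80 Hz, 50 Hz
preserved); and automatic artifact rejection as a peak-to-peak epoch gate
(default 100 µV) with an error if fewer than half of an element's epochs
survive. The exact clinical rejection rule is proprietary; an amplitude
gate is transparent and, at realistic SNR, the kernel is insensitive to the
choice. Noise-free verification runs skip the filter: the synthetic
templates are band-limited by construction, and the 3 Hz high-pass removes
genuine low-frequency template content (~2 % of the measured density), so
the filter is validated against its frequency-response contract instead.

## The RAD statistic

RAD = (mean over the pre-stimulus baseline − minimum over the 50–90 ms
trough window) / element area, in nV/deg². The baseline window is
[−10, 0] ms (short, drift-robust, configurable). Ties in the trough
minimum resolve to the earliest sample. Within-ring pooling is
area-weighted (equivalent to total amplitude over total area); cross-ring
combinations — R3+R4, and each sector as the mean of its R2/R3/R4 portion
densities — are unweighted means of pooled densities, following the stated
"averaged RAD values between" rule. Whether clinical software pools
unweighted or area-weighted within rings is unstated; both modes are
implemented, area-weighted by default (for the uniform fields used in
verification the two coincide).

## Cohort statistics

- Group summaries: mean and SD (n−1).
- ANOVA: classical two-group one-way F with df (1, n₁+n₂−2); the
  summary-statistics form is algebraically identical when the summaries come
  from the raw data (property-tested), and is what allows a patient table to
  be compared against published control summaries when raw control data are
  not deposited. Zero pooled variance with unequal means yields F = ∞,
  flagged rather than hidden.
- Normative limits: computed mode uses the one-sided lower 95 % bound of
  the control mean, mean − t(0.975, n−1)·SD/√n. The published limits are
  close to but not exactly reproducible by any single mean±k·SE/SD rule, so
  a supplied mode passes published limits through verbatim and is the
  default for the bundled cohort. Classification is strictly below-limit
  (a value at the limit is normal); percentages are rounded to 1 dp only in
  the report layer.
- Regressions: OLS with RAD as the dependent and GCL-T as the independent
  variable (the direction the published estimates satisfy via
  slope = r·SD(RAD)/SD(GCL)); 95 % CI from t(0.975, n−2); R² = squared
  Pearson r.
- Trends: per-group OLS over unit-coded region levels (0, 1, 2, …), with
  the group×index interaction p from a pooled model. For balanced complete
  data the individual-level slope equals the slope on level means (tested as
  an identity). Intercepts are reported at the first level.
- Significance threshold 0.01; p-values below 0.001 print as "<0.001".

## Bundled reference cohort

The package ships a published 21-eye OAG cohort (per-eye regional values at
1 dp), the published control summaries (3 dp) and normative limits, and the
published regression estimates. Recomputing from these printed values
reproduces all group means and SDs exactly at 3 dp, both abnormality
percentages used as checks (95.2 % and 71.4 %), and both GCL trend slopes at
2 dp. Quantities the printed precision cannot pin down exactly are handled
with explicit bands: the summary-form F differs from the published value by
up to ~0.05 (control summaries are 3-dp-rounded), and recomputed R² can
differ by ~0.01 from the published 2-dp values (individuals are
1-dp-rounded). Three source inconsistencies are recorded in
`reference.FIXTURE_NOTES` and surfaced in every report: a dropped digit in
one printed summary mean (restored to 20.190), a printed ST-sector abnormal
count (19) that disagrees with the printed individuals vs limit (18), and
published mfPhNR ring-trend coefficients that are not reproducible from the
ring means (the report therefore does not emit them).

## Synthetic cohorts

`simulate_cohort` draws (RAD, GCL-T) per region pair and eye from a
bivariate normal with the group's means/SDs and a target correlation
r = √R²; the defaults are the bundled reference moments, i.e. the study's
own conditions (20 controls, 21 patients). The same r is applied to both
groups (published correlations exist only for patients). Regions are drawn
independently of each other — real regional values are strongly
cross-correlated within an eye — and normality is exact by construction, so
passing recovery tests demonstrate estimator correctness, not robustness to
real-data violations. `simulate_gcl_grid` solves the regional-mean
constraints by minimum-norm least squares around the grand target mean:
all supplied area and/or sector targets are met exactly in the noise-free
grid and in expectation under added noise.

## Problem sizes and numerical choices

Verification runs use the full 60-element dartboard with order-8 (255-step)
sequences in tests and a complete order-12 (4095-step) recording in the
acceptance script; cohort recovery uses n = 2000 for the convergence check
and 200 replicates at n = 21 for small-sample dispersion — sizes chosen so
the whole suite runs in seconds while leaving Monte-Carlo error well inside
the asserted bands. Weighted pooling sorts members by element id so sums
are order-stable; lstsq (min-norm) handles the underdetermined grid
constraints; all simulator randomness flows through one explicit
`numpy.random.default_rng` seed per call.

## Limitations

- No ocular artifact realism (blinks, saccades, drift, line noise) and no
  second-order kernels; the artifact gate is verified on injected square
  spikes only.
- No OCT B-scan segmentation: the package consumes thickness grids. Scan
  quality criteria are acquisition-time concerns and not computable here.
- No RGC-displacement correction: the central region definitions are taken
  to absorb foveal displacement, as in the source analysis.
- The sector tessellation asymmetry (5/4 wedges) means sectors contain
  slightly different element counts; densities are area-normalised, so this
  does not bias regional values.
- No multiple-comparison correction beyond the 0.01 threshold, matching the
  analysis being reproduced.
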