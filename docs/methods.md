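# Methods

## Scope and design

`cochleaquant` implements the quantification layer of a cochlear
gene-therapy experiment as independent, composable modules: synthetic
raw-data generation with ground truth, 3D image analysis, arc
morphometry, cochleogram/place-frequency mapping, ABR/DPOAE feature
extraction, behavior scoring, and the statistical tests used for group
comparisons. Every module is validated against the generators, whose
truth tables are exact by construction.

## Arc morphometry

Hair cells in LINC-complex mutants keep their overall shape while the
nucleus slides apically, so nuclear position is measured *along the
cell*, not in straight-line distance. Three landmarks per cell —
apical surface (cuticular plate) A, nucleus centroid N, basal end B —
define a unique circle (their circumcircle, in the plane they span);
the statistic is the arc length A→N measured along the arc that passes
through N, with A→N / A→B as a normalized variant. Landmarks are
scaled from voxel indices to µm before fitting (voxel centers at
index × voxel size, 0-based).

Numerical choices: collinearity is declared when the triangle area is
below 1e-9·|AB|² (scale-free; prevents the circumradius from blowing
up) and the statistic falls back to straight segments. Duplicate
landmarks are rejected. Arc lengths are closed-form (R·Δangle); the
test suite cross-checks them against numerical quadrature of the
circle parameterization at 1e-9 and asserts rigid-motion invariance.

## Synthetic cochlea stacks

`gen_cochlea_stack` renders one IHC row and three OHC rows of cells
along a straight cochlear axis (a planar parametric curve in the
general case; curvature is irrelevant to the quantities under test,
and a realistic spiral is out of scope). Each cell is a soft-edged
tube (myosin-VIIa channel, radius 3 µm) along a circular arc of chord
15 µm and sagitta 1 µm, so every cell genuinely requires an arc fit.
The nucleus (DAPI) is a 2.2 µm-radius ball placed *on* the cell arc at
a programmed arc distance from the apical end, with a brighter rim at
the nuclear envelope — mimicking peripheral chromatin and giving the
DAPI maximum at the nuclear periphery, which is what centers the
FLAG/DAPI line profiles. GFP fills the nucleus with a per-cell
intensity drawn from "on" (transduced, mean 60 a.u.) or "off" (mean
8 a.u.) normal distributions; FLAG is a Gaussian shell at the nuclear
boundary of transduced cells. Gaussian sensor noise (default SD
3 a.u., clipped at zero) is added everywhere; the default
DAPI-amplitude-to-noise ratio is 20.

Genotype presets (`study_params`): WT — all OHC survive, nuclei at
10 µm from the apical landmark (jitter SD 0.3 µm); KO — OHC nuclei
shifted 3 µm apically and OHC survival following
p(s) = clip(0.8 − 0.6·s/L) so that loss is strongest toward the base
(matching high-frequency-first hearing loss); KO_treated — 90% of
cells transduced, transduced cells keep WT position and survive. The
3 µm shift and the survival-gradient parameters are free parameters of
the simulation — the real effect sizes are not published numerically —
chosen to be comfortably measurable yet small relative to cell length.
Dead cells are simply not rendered. Truth tables store per-cell type,
row, survival, transduction, landmark coordinates, exact arc distance,
and axial position; a noiseless render re-measured by the full
segmentation→classification→arc-fit chain recovers truth arc distances
to better than one voxel diagonal (asserted in the tests).

What the generator does *not* emulate: optical PSF anisotropy,
photobleaching, spectral bleed-through, tissue deformation, or manual
landmark placement. Passing tests therefore demonstrate correctness of
the measurement chain, not robustness to every real-world imaging
artifact.

## Image analysis

Nucleus segmentation is Otsu thresholding on DAPI (parameter-free)
followed by watershed on the Euclidean distance transform (anisotropic
sampling = voxel size); markers are local maxima of a lightly smoothed
distance map (σ = 1 voxel, which keeps plateau tops from seeding twice),
and regions below 8 µm³ are dropped. Labels are re-ordered by centroid
so segmentation is deterministic.

Cell typing projects each nucleus centroid onto the pillar-cell
polyline and clusters the signed lateral offsets (gaps larger than half
the row spacing split clusters); negative offsets are the IHC row,
positive clusters are OHC rows 1–3 in increasing offset. Known row
offsets can be supplied instead of estimated. A centroid exactly
equidistant between two row centers goes to the lower row index and is
flagged `ambiguous`; cells with no myosin signal are flagged
`no_myosin`, never dropped. Apical/basal landmarks are the centroids of
the top and bottom depth slabs of the cell's myosin column (voxels
within 4.5 µm of the nucleus in the lateral plane). The automated row
model replaces what was a manual identification step in practice and is
validated only against synthetic truth.

GFP positivity uses the control-animal convention: per cell type,
µ_c and σ_c are the mean/SD of control nuclear intensities;
positive ⇔ I > µ_c + 2σ_c, and reported intensities are
(I − µ_c)/µ_c — reconciling "background subtraction by the control
mean" with "normalization to the control" in one number that reads as
fold-change over control. A pooled (both-types) cutoff is available as
an option. Positivity is invariant under a global acquisition gain
applied to both specimens (asserted as a property test).

## Cochleograms and the place–frequency map

Detections are projected to the nearest point of the apex-first
polyline (perpendicular foot or vertex; ties take the smaller arc
length; projections beyond the ends clip to the terminal bins) and
counted in 100 µm bins. The final partial bin is kept with its density
rescaled to per-100 µm so the apical/basal extremes are not lost.

The place–frequency map is logarithmic: percent-from-base
d = 156.5 − 82.5·log₁₀(f/kHz), distance-from-apex = (1 − d/100)·L.
The organ length L defaults to 5.13 mm — the reference organ length of
the underlying map — which puts the 12 kHz place at 1.669 mm from the
apex, inside the 1.63–1.69 mm window used for regional OHC counts.
Frequencies mapping outside [0, 100]% are rejected with the admissible
range. Regional density (`region_density`) averages bin densities over
a window (default 60 µm) with overlap weights; the window width is a
parameter because counting bins (100 µm) and scoring windows need not
coincide.

## ABR

Simulated averaged traces carry a stimulus-locked P1/N1 complex
(difference of Gaussians, unit peak-to-peak, P1 width 0.25 ms) for
intensities at or above the true threshold: peak-to-peak amplitude
1.0 µV + 0.05 µV/dB above threshold, P1 latency 1.5 ms − 0.01 ms/dB.
Sweep averaging is applied analytically — the averaged-trace noise SD
is noise_sd/√n_sweeps (default 2 µV / √512 ≈ 0.09 µV) — and the 1/√n
contract is verified empirically across traces. Noise is band-limited
(Gaussian-smoothed white noise, correlation ≈ 0.5 ms), as in a real
averaged recording after band-pass filtering; the record keeps an 8 ms
pre-stimulus baseline.

Detection operationalizes the "reproducible waveform" judgment:
response-window peak-to-peak > k·SD(baseline), k = 4. The response
window is onset + 0.5–3.0 ms — tight around where P1/N1 can occur.
This matters quantitatively: the peak-to-peak of band-limited noise
over a long window approaches ~3.5σ, so a window much wider than the
physiological P1/N1 range makes any SD-multiple criterion fire on
noise. With the default geometry the per-trace false-positive rate is
≈10%, and the monotone threshold rule (threshold = lowest intensity
detected along with *all* higher intensities, so isolated
false positives below a gap are ignored) reduces the chance of a
>5 dB threshold error to ≈1%. Undetectable series are censored and
encoded as grid max + step (95 dB SPL) with an explicit flag, so group
statistics remain computable without silent sentinel values.

P1 is the first local maximum after onset in the search window, N1 the
first local minimum after P1; latency is P1 time minus onset, amplitude
is V(P1) − V(N1). Flat or featureless traces return a flagged,
feature-less result.

## DPOAE

Spectra contain primaries f1 = f2/1.2 and f2 and, above the programmed
threshold, a 2f1−f2 component at noise floor + 15 dB + 1 dB/dB,
power-summed with the per-bin noise (floor −10 dB SPL, SD 3 dB). The
extractor reads the bin nearest 2f1−f2, estimates the noise floor as
the mean of 5 bins per side (skipping 2 guard bins and any
primary-tone bins), and declares detection at ≥ noise + 6 dB — a
criterion chosen (and exposed in config) because the underlying
recording convention does not fix one; with 3 dB bin noise it yields
≈3% false positives. DPOAE thresholds use the same monotone/censoring
rule as ABR.

## Behavior

Freezing is scored on the activity channel (fraction of pixels changed
per frame, or the equivalent tracking-software export): maximal runs
below θ = 0.01 lasting ≥ 1 s. Both defaults are stand-ins — the
empirical threshold was set by manual video inspection and is not
published — and both are config-exposed; detection is monotone in θ by
construction. Day-2 fear-conditioning summaries use two 60 s bins
anchored at the tone onset (90–150 s and 150–210 s), reporting mean
activity and cumulative freezing per bin with bout overlap split
across the boundary.

The behavior generator renders hearing-phenotype mice as freeze bouts
(3–10 s) totaling freeze_fraction × tone duration starting at tone
onset + latency, and deaf-phenotype mice as the same total freezing
placed uniformly through the session; truth bouts are snapped to the
frame grid so they match the rendered activity channel exactly.

Open field: rotations accumulate the signed angle of the center→nose
vector, counting one CW/CCW rotation per full ±360° with the
accumulator reset after each counted turn and on direction reversals
(partial turns do not carry across reversals; a 1e-6 rad tolerance at
±2π absorbs float error at exact full turns). Distance is the summed
center-point displacement in cm; center time is the time inside the
central 0.4 m² square of the 2.5 m² arena, over the 300–900 s
analysis window. Each frame covers the interval to the next frame, so
a full-window stay scores exactly the window length.

## Statistics

Pearson r with two-tailed p from t = r√(n−2)/√(1−r²) on n−2 df
(scipy); zero-variance input is rejected. Holm–Šidák follows the
step-down convention adj_(i) = 1 − (1 − p_(i))^(m−i+1) on the sorted
p-values with monotone enforcement and a cap at 1, returned in input
order — verified against a brute-force oracle and statsmodels. The
two-way ANOVA implements the balanced case only (classical
sums-of-squares; F = MS_effect/MS_within), rejecting unbalanced
designs: the per-frequency group comparisons it serves are balanced,
and mixed/unbalanced models are deliberately out of scope. An all-equal
input reports F = 0 with a `degenerate` flag. Type-I error of the null
factor is calibrated (0.03–0.07 at α = 0.05 over 1000 simulations) in
the tests. Paired before/after contrasts use the paired t-test on
differences (scipy), with zero-variance differences flagged.

## Pipeline

`pipeline.run` executes stages in dependency order from one YAML
config; every stage echoes its parameters (defaults included) into the
manifest, CSV outputs use a fixed column order and 6-significant-digit
floats so reruns with the same seed hash identically, and a missing
prerequisite aborts naming the first failing stage. The demo
configuration (12 cells/row) runs the full chain in well under a
minute on one CPU.

## Problem sizes used in validation

Parameter-recovery checks run at deliberately modest sizes chosen to
give tight Monte-Carlo error while staying quick: 17 cells/row stacks
(≈51 OHC/group) × 5 seeds for the 3 µm shift recovery; 100 ABR series
and 200 pure-noise DPOAE spectra for threshold/false-positive rates;
1000 simulations for ANOVA null calibration; 10 seeds for freezing-bout
IoU. At these sizes the expected estimator errors are an order of
magnitude below the asserted tolerances.

## Known limitations

* The cell classifier assumes the row layout of the healthy organ of
  Corti (1 IHC + ≤3 OHC rows roughly parallel to the pillar polyline);
  severely disorganized epithelia would need manual row models.
* Landmarks come from myosin blob extents; on real data with uneven
  staining, manually clicked landmark CSVs are the safer input path.
* The ABR detector is an amplitude criterion, not a human
  reproducibility judgment; its false-positive behavior depends on the
  noise bandwidth of the recording chain.
* Only balanced two-way ANOVA is provided; unbalanced designs and
  mixed-effects models (e.g. longitudinal weight gain) are out of
  scope.
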