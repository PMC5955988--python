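# Methods

## Scope and conventions

`onhlab` implements the measurement chain of a chronic intermittent
IOP-elevation study as reusable, testable components. All volumes are
indexed `(b_scan, a_scan, depth)`; the depth axis increases posteriorly
with origin 0; surface elevation is anterior-positive; ONH depression
`D = h_o − h_i` is positive for a posteriorly bowed ONH (a declared sign
convention — the defining study reports the magnitude without fixing a
sign). Lengths are µm inside volumes and mm for whole-eye geometry;
voltages are µV; times are ms with flash onset at 0.

## Synthetic phantoms

No imaging or electrophysiology data accompany the study this chain
addresses, so every stage is validated against generators with programmed
ground truth.

**OCT phantom.** A layered retina is rendered under an analytic ILM
surface: tilt plus a radially symmetric pit, either a Gaussian
`d·exp(−r²/2σ²)` (default) or a tanh-walled crater (flat floor of radius
σ, wall width σ/3). Both are smooth and metric-evaluable in closed form;
the true 150/500 µm depression is recorded alongside each volume. Bands
(NFL+GCL 40 µm, GCC remainder 40 µm, outer retina 120 µm, then a 16 µm
RPE band) are rasterised with sub-pixel partial-volume coverage, so the
geometric boundary positions are exact. Axial motion jitter is a smoothed,
detrended random walk applied per B-scan *before* rasterisation — the
recorded shifts are exactly what the volume contains. Speckle is
multiplicative gamma noise parameterised by a single contrast (default
0.35, plus a 0.01 additive floor); vessels are line segments whose
footprint attenuates everything below the ILM 4-fold. The default grid is
256 × 256 × 512 voxels at 8 µm lateral / 2 µm axial spacing — a desk-scale
stand-in for the instrument's 1000 × 1000 A-scan acquisition over ~2 mm²
(the instrument's axial pixel pitch is not published; 2 µm/px is declared,
not inferred). What the phantom does *not* emulate: real ONH anatomy
(Bruch's opening, cup asymmetry), lateral motion, signal roll-off in
depth, or blink artifacts — passing tests bound algorithmic error, not
anatomical model error.

**ERG generator.** Noiseless waveform = baseline − A_a·G(t−t_a) +
A_b·G(t−t_b) + OP packet, with Gaussian lobes (defaults 200 µV @ 15 ms,
width 6 ms; 600 µV @ 55 ms, width 20 ms) gated to zero before flash onset;
only peak-based features are extracted downstream, so lobe kinetics are
deliberately generic. The OP packet is an in-band sinusoid (120 Hz) under
a cosine-tapered 20–60 ms window. Sampling is 2 kHz over 1 s with a 500 ms
pre-stimulus period. Ground-truth features apply the peak-to-peak
definitions to the noiseless waveform on the sample grid, so truth and
estimator share the same definitions but not the same code path.

**Axon fields.** Homogeneous Poisson points in an ellipse (defaults
0.28 × 0.25 mm semi-axes, area ≈ 0.22 mm²; density 384 000 axons/mm²)
with i.i.d. Bernoulli degeneration labels.

**Study simulator.** Endpoint values are cell mean + between-subject
effect + residual, for 6 subjects × 2 eyes × weeks {1, 5, 9} ×
{pre, loop, post}. Programmed means follow the study's printed group
values: loop-on depression (89.3, 206.3, 214.3) µm against pre/post ≈
21 µm; a loop-on ERG multiplier declining (4.0, 3.5, 3.0) across weeks
(the decline is reported as a trend without printed values; the 3.5/3.0
are this package's choice); the measured IOP profile per procedure.
Depression noise is split 16 µm between-subject / 20 µm residual so a
single cell's SD reproduces the printed 25.6 µm. A full study would
contain ~100 volumes (≈14 GB), so raw volumes and traces are materialised
lazily per cell with the cell's endpoint programmed in, while the tidy
endpoint table is returned eagerly.

## OCT registration and segmentation

Registration estimates consecutive-pair axial shifts by Fourier-upsampled
(×100) cross-correlation of per-B-scan mean A-line profiles, demeaned and
band-limited (Gaussian σ = 1 px) first — the sub-pixel correlator is only
unbiased for band-limited signals. Pairs whose normalized correlation peak
falls below 0.3 contribute no shift and flag their B-scan. Cumulative
shifts are linearly detrended (drift is indistinguishable from tilt;
higher-order detrending would eat real surface shape), then applied as
exact Fourier phase ramps. On noiseless phantoms the detrended shift
sequence is recovered to <0.1 px RMS. Two couplings remain by design of
the consecutive-profile metric: speckle adds ~0.5 px of per-B-scan stripe
noise at default contrast, and a pit occupying a large fraction of the
field leaks surface shape into the mean profile. Both average out of the
ring-averaged depression metric (net bias ≈ −1 µm at study geometry), but
on fields much smaller than ~2 mm the leakage grows — registration is
trusted at the acquisition scale it emulates.

Surface segmentation is a dynamic-programming minimum-cost path through
the axial gradient of the log-intensity image (log makes multiplicative
speckle additive and vessel shadowing a constant offset), with a ≤2 px
jump between neighbouring A-scans and parabolic sub-pixel refinement; a
+0.5 px offset converts gradient-peak sample coordinates to geometric
boundary depth (voxel *i* spans [i, i+1)). The ILM is the global
dark-to-bright path; the RPE is the remaining dark-to-bright step
constrained ≥40 µm below the ILM. This is a simplified stand-in for the
graph-based layer segmentation the instrument software modifies
(unpublished); the tested contract is what matters: exact recovery on
noiseless edges, ≤1 axial px RMS at default speckle. A-scans whose maximum
gradient stays below 6 robust sigmas of the gradient field are masked
invalid, never guessed. Smoothing spans neighbouring B-scans (σ = 1 px),
which presumes registered input — the documented precondition.

## ONH metrics

The centre is either operator-provided (mirroring the study's manual
choice of the vessel convergence point) or auto-detected as the minimiser
of mean elevation over a 150 µm disc; maps whose pit is shallower than
10 µm are refused rather than mis-centred. Elevation is sampled along 360
rays by bilinear interpolation; the depression averages each ray over a
±10 µm annulus at 150 and 500 µm (point radii are specified by the study;
the annulus adds noise robustness and changes the Gaussian-pit metric by
<0.05 µm). At least 75% of rays must be valid at both radii, otherwise the
metric refuses and names the masked rays.

Circular-scan thickness resamples the volume on a Ø 1 mm circle (3000
samples), segments ILM/RPE and the two inner band edges (bright-to-dark
polarity, searched 15–65 µm and 55–105 µm below the ILM — phantom-band
windows standing in for the study's manual delineation, which cannot be
replicated), and averages boundary distances outside the vessel mask. The
mask thresholds the sub-ILM en-face projection at the 15th percentile
*capped at 0.6× the median* (shadows attenuate ~4-fold; speckle does not
— without the cap a vessel-free map would always lose 15% of its circle),
then dilates by 3 px.

## ERG features

Averaging precedes extraction (features of the mean trace, not the mean
of features; the order is unstated in the defining study and documented
here as a choice). The a-peak is the earliest local minimum (±2-sample
prominence) in the 5–40 ms window that is both below baseline by 3
pre-stimulus SDs and within 3 SDs of the window minimum — the two guards
keep shallow noise dips on the descending flank from posing as the trough
while preserving "first negative peak" semantics; their cost is that
genuine a-waves smaller than ~3 noise SDs are reported as not found. The
b-peak is the maximum after the a-peak up to 150 ms, on the unfiltered
trace. The OP filter is frequency-domain with unity gain in 75–300 Hz and
5 Hz raised-cosine transitions, hence exactly zero-phase; the RMS window
20–70 ms is inclusive at both ends.

## Eye model

The globe is a spheroid with semi-axes (axial/2, transverse/2,
transverse/2). Rays are straight; refraction is out of scope. The cone
apex defaults to 3.0 mm behind the anterior pole — the posterior nodal
point of the schematic rat eye — rather than the anatomical pupil plane
(~1 mm): a stimulus focused at the pupil diverges inside the eye as if
from the nodal point, and this is the standard mapping from stimulus
visual angle to retinal extent when the optics are not traced explicitly.
With the apex at the anatomical pupil the baseline→elevated area change
computes to ~7%; at the nodal point it is ~10.9%, consistent with the
~11% the full optical accounting (including corneal-curvature change)
yields. The cap area integrates a triangulated (α, φ) ray grid
(512 × 256 default; halving the mesh moves the area <0.05%, and the
spherical-cap closed form is matched to 0.1% when the axes are equal).
The tolerance quoted for the ~11% figure (±2 percentage points) absorbs
the unmodelled corneal effect and the unpublished pupil/nodal geometry.

## Axon estimation

Cells are 50 × 50 µm, half-open (edge points counted once), anchored at
the bounding-box corner; only cells fully interior to the boundary are
eligible, and a systematic-random subset (random start, regular stride —
dispersed cells, mirroring stereological fixed-grid practice; the study
does not say whether its 20% was contiguous) is selected to match the
target fraction within one cell. Density = counts / sampled area; totals
= density × nerve area. The estimator is unbiased for homogeneous Poisson
fields (verified over 200 seeds); at full sampling of a non-tiling
boundary the sampled area necessarily falls short of the nerve area by
the boundary-cell remainder. An empty sample yields density 0 with the
degenerating percentage flagged undefined rather than NaN.

## Statistics

The RM-ANOVA partitions sums of squares on the balanced subject × cells
array by inclusion–exclusion over marginal means; each within effect is
tested against its subject-by-effect interaction. This direct partition
(rather than a general mixed-model fitter) keeps every number checkable
with explicit loops, and the one-way F is tested to 1e-8 against such an
oracle; two-way results match pingouin to 1e-6. Epsilon per effect comes
from the orthonormal-contrast (Helmert, Kronecker products for
interactions) covariance of the effect's collapsed cells, clamped to
[1/df, 1]; the "apply GG when ε < 0.75" rule is the default and
config-exposed (`always`/`never`/`threshold`). Two properties worth
stating precisely: GG-corrected p exceeds uncorrected p in the rejection
regime (small p), but the ordering can flip near F ≈ 1, where shrinking
both dfs thins the upper tail — the conservativeness guarantee is
asserted for p ≤ 0.10; and with n = 6 subjects the GG-corrected
higher-order interactions are noticeably conservative (null rejection
~0.02), while main effects stay within [0.03, 0.07]. Post hocs are paired
t-tests between factor levels with Bonferroni multiplication by the
number of pairs in that factor's family (the family definition is this
package's documented choice). Summaries use the n−1 SD and SD/√n SE;
single-observation cells are flagged, not dropped.

## Problem sizes and numerical choices

Phantom pipelines run at 256 × 256 × 512 (the desk-scale default; the
full 1000 × 1000 geometry is a parameter choice away), ~15 s per volume
end to end; the depression-recovery check uses 20 seeds. Monte-Carlo
cross-checks use 10⁶ samples. Interpolation is bilinear for maps and
circles, cubic-spline-free; sub-pixel refinement clamps parabola vertices
to ±0.5 px; degenerate inputs (flat maps, all-invalid surfaces, singular
covariances, empty samples) raise typed errors with the offending cells
named rather than propagating NaN.
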