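# Methods

This note documents the models, estimators and numerical conventions the
package implements, the design choices that were genuinely open, and what
the synthetic phantoms do and do not establish about real data.

## Cryo-fluorescence redox pipeline (`redox3d`)

**Model.**  Two co-registered 3D volumes (10 µm isotropic voxels) hold the
NADH and FAD autofluorescence channels of a snap-frozen eye.  The
mitochondrial redox ratio is computed voxel by voxel as NADH/FAD wherever
the FAD signal is at or above a floor (default: 1% of the FAD channel's
Otsu threshold; the floor only guards against division blow-ups in empty
background and removes no retinal voxels in practice).  The ratio is a
concentration-ratio quantity, so it is invariant under any common gain
applied to both channels; this scale invariance is asserted by tests.

**Shell segmentation.**  The retina forms a sphere-like fluorescent shell.
It is segmented from the summed channels by Otsu thresholding, one
morphological closing (6-connected structuring element), and keeping the
largest connected component.  The closing is hysteresis-guarded: a voxel
it fills is kept only if its summed intensity reaches the midpoint of the
two Otsu class means.  This heals noise dropouts inside the shell but
never annexes background voxels at concavities of the discretized sphere,
so a zero-noise phantom is recovered *exactly*; at voxel noise CV 0.05 the
Dice coefficient against truth stays above 0.999.  A volume without a
two-population intensity structure (all background) raises an analysis
error rather than returning a spurious mask.

**Projection and mean.**  The masked ratio volume is maximum-intensity
projected along z; projection columns with no contributing voxel are
excluded from the foreground.  The mean of the projected image is offered
in two scopes:

* `full_frame` — the literal frame-normalised double sum over all
  Nx × Ny pixels (background contributing 0), kept for conformance and
  checked against a brute-force double loop;
* `foreground` (default) — the mean over retina pixels only.  Frame
  normalisation drags the mean toward zero for any frame larger than the
  eye; group means of order 0.6–1.0 are only meaningful on the foreground
  scope, which is therefore the default.

**Known estimator bias.**  The maximum of n noisy samples overestimates
their common mean.  With per-channel voxel noise CV σ the voxel ratio has
CV ≈ √2·σ, and a projection column crossing the shell twice contributes
tens of voxels, so the projected mean sits ≈ 1.3–2.3 ratio-SDs above the
true ratio — about +3–5% at the default CV 0.02, growing with noise.  The
pipeline reports the measurement as defined rather than debiasing it; the
property suite asserts the bias is nonnegative and monotone in noise, and
recovery tests allow for it.  Consequences: recovered phantom means are
biased high by ~0.03–0.05 at CV 0.02 (e.g. 0.968 for a true 0.92), while
*differences between groups imaged at equal noise* are nearly unaffected
and the group ordering is preserved.

**Oxidative shift.**  `oxidative_shift(test, ref) = 100·(ref − test)/ref`;
positive values mean the test group is more oxidized.  For the
representative group means 0.66 (dystrophic) and 0.92 (control) this is
28.3%, i.e. 28% to the nearest integer.

## Cryo phantom (`phantom.make_cryo_phantom`)

The phantom is a centred spherical shell in a cubic volume of
`ceil(eye_diameter / voxel_size)` voxels per axis.  Defaults: a 2 mm globe
at 10 µm voxels (200³), i.e. a 1:3.2 scale model of a ~6.4 mm rat eye;
shell outer radius 950 µm and thickness 50 µm, the scaled equivalent of
the ~170 µm retinal thickness measured at p30.  Shell voxels draw
Normal(channel mean, CV·mean) truncated at 0, background likewise around
a low mean (5 AU); channels are independent.  Three packaged profiles fix
the channel means so the true ratios equal the representative group means
(SD 0.92, P23H 0.66, P23H-PBM 0.97).  The shell is spherically symmetric
and the noise spatially white — real retinas are neither, and real
autofluorescence has depth-dependent attenuation that is deliberately not
modelled — so phantom recovery validates the *estimator chain*, not
instrument physics.

## OCT LRP analysis (`octlrp`)

**Registration.**  B-scan replicates are aligned to the first scan by the
integer (axial, lateral) shift maximizing the circular FFT
cross-correlation of mean-subtracted images, then averaged pixelwise.
Planted integer shifts are recovered exactly in the noiseless case, and
averaging n speckle realizations shrinks per-pixel noise ~√n.

**LRP and boundary calls.**  The LRP is the mean over a 100-pixel lateral
window at each axial row, with depth = row × axial scale (row 0 =
vitreous side).  Boundary detection assumes the canonical band sequence
bright inner retina / dark ONL / bright IS-OS–RPE complex: the ILM is the
first rising half-max edge (half level between the vitreous level,
estimated from the first three samples, and the profile maximum), BM the
last falling one, and the ONL interfaces the falling/rising half-height
edges into and out of the deepest trough between them.  All edges are
linearly interpolated to sub-pixel depth; all thresholds are relative, so
calls are invariant under global intensity scaling.  Missing landmarks
(flat profile, fewer than two bright bands, no trough) raise analysis
errors naming the landmark.  The half-height rule is a choice — the
field's LRP papers do not pin a boundary operator — and is validated by
phantom-truth recovery: each interface within ½ axial pixel noiseless,
within 1 pixel at speckle CV 0.1 after 40-scan averaging.

**Thickness protocols.**  Total thickness = BM − ILM averaged over 10
windows at ±50·k px (k = 1…5) around the ONH column; ONL thickness =
ONL/IS-OS − OPL/ONL at ±88/176/264/352/440 µm, with µm offsets rounded to
the nearest column.  The ONH column is an input (the phantom provides
it); a convenience auto-detector picks the column with the least
above-half-max reflectivity.  Longitudinal cohorts are summarized as
per-age mean ± SE with a strict-decrease flag and an optional per-age
Welch comparison between two groups.

## OCT phantom (`phantom.make_oct_bscan`)

Each A-scan is piecewise constant over the configured bands (row r takes
the band containing depth r × axial scale, so noiseless columns step
exactly at the interface rows), multiplied by Normal(1, CV) speckle —
a variance-controllable simplification of Rayleigh OCT speckle.  Columns
within the ONH halfwidth collapse to the vitreous level (excavation);
because that contamination is affine in the window mean, the relative
edge estimator is unaffected.  Packaged profiles place the ILM at
30.5 µm with totals 178.1 µm ("PBM-p30") and 169.2 µm ("sham-p30"), the
measured p30 group means used as configured ground truth.  Interfaces are
deliberately placed at non-integer pixel depths: there the half-height
estimator is near-unbiased, whereas integer placement puts the interface
exactly between samples — the worst-case half-pixel quantization.
Acquisition jitter is emulated by circular integer shifts of replicates
(`make_oct_replicates(..., jitter_px=3)`), which registration must undo.

## ERG (`erg` and `phantom.make_erg_trace`)

**Waveform model** (invented, as a recovery oracle): the trace is
−A(I)·g_a(t) + (B(I) − A(I))·g_b(t) + Normal(0, σ) with Gaussian lobes
peaking at the a/b implicit times (widths a_time/3 and (b_time −
a_time)/4, narrow enough to be separable), and amplitudes following the
Naka–Rushton saturation S(I) = Iⁿ/(Iⁿ + Kⁿ) — the standard monotone
saturating intensity–response form.  By construction the ISCEV
measurements recover A as baseline→trough and B as trough→peak.
Defaults: a 150 µV, b 300 µV saturated; times 15/60 ms; K = 500
mcd·s/m²; n = 1; 2 kHz sampling; flash intensities spanning 100–25,000
mcd·s/m².

**Measurement.**  Baseline = mean over [−20, 0) ms; a-wave trough
searched in (0, 50] ms and clamped to 0 unless the deflection exceeds
twice the baseline noise SD; b-wave peak searched in (trough, 150] ms.
Before extremum picking the trace is band-limited by a 1.5 ms moving
average (clinical amplifiers low-pass around 300 Hz); without it,
extrema picked off raw noise bias both amplitudes upward by ~5–6% at
noise SD = 5% of the a-wave, versus ~1–2% with it, while the noiseless
recovery error stays under 0.5%.  `smooth_ms=0` measures the raw trace.
Flicker amplitude folds the trace into stimulus-period phase bins
(≥5 cycles required), averages cycles, and returns peak-to-trough of the
averaged cycle; a sinusoid of amplitude A reports 2A and unlocked
components average toward zero.

## Histomorphometry (`histo`)

Rows of ONL nuclei are counted as maximal runs of image rows whose
occupancy within the lateral window is ≥ 50% — an operationalization of
by-eye row counting chosen so the phantom's configured row count is
exactly recoverable; it is checked against a brute-force run-scanning
oracle on every window of a random mask.  Real-micrograph nucleus
segmentation is out of scope.  The nuclei-mask phantom draws one row of
disjoint circular nuclei per configured row (band height = rows ×
nucleus diameter at 1 µm/px).

## Group statistics and dose (`cli_io`)

Groups are reported as mean ± SE (SE = sd/√n, n−1 denominator; a single
observation has SE 0 by convention), with Welch's unequal-variance t as
the only two-group comparison — heavier designs (mixed-model ANOVA,
MANOVA, Kruskal–Wallis) are deliberately left to general statistics
packages.  `energy_density` converts irradiance × duration to J/cm²
(mW → W), bilinear in both factors.

## Problem sizes, determinism, limitations

Phantom recovery runs use 200³ cryo volumes, 40-replicate 250×1000-px
B-scans and 100-replicate ERG traces; the test suite uses 80³ volumes
and 700-column scans, sizes at which every stochastic assertion holds
with wide margin.  All generators take one explicit integer seed and are
bit-reproducible; no global random state is used or mutated.  Known
limitations: the MIP noise bias described above; multiplicative-Gaussian
speckle instead of Rayleigh; no optical PSF, attenuation or spectral
unmixing; frozen-tissue ratios need not equal in-vivo ratios, so only
trends and group contrasts transfer.
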