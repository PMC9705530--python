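# Methods

This note documents the models, defaults and numerical choices behind
`volca`, and what the synthetic benchmark does and does not establish.

## Recording model and geometry

A recording is a nonnegative array indexed `(t, z, y, x)` with physical
metadata: voxel size `(dz, dy, dx)` in µm, volume period in s, planes per
volume. The defaults mirror a 20× light-sheet configuration: 20 planes at
10 ms exposure (5 Hz volumetric rate), 666 µm lateral field over 512
binned pixels (1.3 µm lateral voxel), 3 µm plane spacing (60 µm axial
coverage). Voxel `(z, y, x)` sits at `index × voxel_size`; stacks acquired
with alternating z-direction are unfolded by flipping every other volume
(the parity is a flag, since acquisition software conventions differ).

## Sensor kernel

The calcium impulse response is the double exponential
`k(t) = (1 − e^(−t/τr)) · e^(−t/τd)`, normalized to unit peak. Sensor
datasheets quote phenomenological half times — time from onset to half of
peak (0.09 s for R-GECO1.0) and time from peak to half of peak (0.78 s) —
not time constants. Because the rise factor keeps growing past the peak,
the naive per-phase conversion `τ = t_half/ln 2` yields a kernel whose
measured half-decay is ≈ 0.90 s, 15% longer than specified. `volca`
therefore calibrates `(τr, τd)` by a 2D root solve so that the *realized*
half-rise and half-decay of the kernel equal the sensor's values (the
naive conversion seeds the solver and is exposed as `halftime_to_tau`).
For the default kinetics the calibrated constants are τr ≈ 0.362 s,
τd ≈ 0.742 s.

## Synthetic movies

`synth` renders, per volume,

```
frame = bleach(t) · stripes(t) ⊙ shift(drift(t),
            cells(t) + pedestal + oof · blur(cells(t))) + noise
```

* **Somata.** Active and static neurons are ellipsoids with weight
  `1 − r²` (compact support), default semi-axes (4.5, 7, 7) µm →
  physical volume ≈ 924 µm³, inside the 710–7605 µm³ morphological band
  used downstream. Centres are rejection-sampled so that normalized
  inter-centre distance ≥ 2 (no somatic overlap).
* **Activity.** Homogeneous Poisson spikes at 0.1 Hz/neuron (the firing
  statistics of these cultures are not characterized; 0.1 Hz gives the
  sparse, uncorrelated transients the extraction assumes), convolved with
  the sensor kernel. Baseline soma fluorescence 50 counts, transient
  amplitude 150, diffuse pedestal 100 (the pedestal represents ambient
  out-of-focus fluorescence; it is bleached and striped with everything
  else and keeps every frame's spatial median positive).
* **Stripes.** Occluders at random (z, y) cast Gaussian attenuation bands
  (default depth 0.3, σ 6 µm) that are constant along +x beyond the
  occluder — shadows propagate with the illumination — and flicker with
  relative amplitude jitter (sd 0.3), which is the temporal variance the
  Fourier filter keys on.
* **Haze.** Each volume receives `0.5 ×` a Gaussian-blurred copy of the
  cell volume (σz = half the 8 µm sheet thickness, 2 µm lateral).
* **Bleaching** is monoexponential (τ = 200 s); **drift** is a smoothed
  random walk, 1 voxel RMS lateral and half that axially (sub-cellular, as
  observed for gel-embedded samples); **noise** is Poisson shot noise plus
  Gaussian read noise (sd 2).

Everything is drawn from `numpy.random.default_rng(seed)`; movies,
ground truth and bead stacks are bit-reproducible. What the generator does
*not* emulate: tissue scattering, non-rigid deformation, indicator
saturation and dye bleaching heterogeneity, correlated network activity.
Passing the benchmark therefore demonstrates the pipeline's mechanics —
artifact removal, source separation, screening, graph construction — not
performance on scattering tissue.

## Preprocessing

Bleach correction divides each volume by its spatial median (every output
volume has median exactly 1). The stripe/background filter takes
`rfftn` over (z, y, x) per volume, computes each coefficient's temporal
variance `E|f − E_t f|²`, and zeroes, for all time points, coefficients at
or above the 99th percentile (linear-interpolation quantile; "<" keeps).
Coefficients whose variance is at float round-off relative to their own
magnitude are genuine constants and are always kept. Because quantiles
commute with monotone maps, thresholding `var` and `log10(var)` selects
the same set — the implementation works on `var`.

The filter is designed for artifact-dominated data (raw trace SNR < 1,
as in real organoid recordings): there the removed top-1% variance modes
are stripe and background drift, and trace recovery *improves* (0.64 →
0.70 mean correlation to planted traces at the dim-neuron benchmark). At
high signal-to-artifact ratio the collective low-frequency neuron signal
itself dominates the temporal variance and the same filter trades signal;
the stripe tests therefore run in the dim-neuron regime, and bright-SNR
benchmarks quantify extraction instead.

## Motion correction

Rigid-only. The template is the voxelwise median of the first 30 volumes;
per-volume shifts maximize the Fourier-domain circular cross-correlation,
restricted to ±(2, 4, 4) voxels (z, y, x), with separable quadratic
interpolation around the integer peak for sub-voxel precision and clamping
to the bound. Shifts are reported relative to the first volume, since the
median template carries an arbitrary sub-voxel offset of its own.
Correction translates each volume by minus its shift with cubic-spline
interpolation (linear interpolation leaves flicker at sharp static edges
that downstream extraction can mistake for activity); out-of-field voxels
take the volume median. Piecewise-rigid patch parameters (strides
(18, 18, 4), overlaps (9, 9, 2), max deviation 5) are recorded in the
pipeline configuration for provenance but not applied — residual
non-rigid motion in these preparations is sub-cellular.

## Extraction

Seeding computes a 6-neighbour temporal-correlation image, smooths it at
`gSig` = (2, 2, 2) voxels, takes strict local maxima above 0.1 and
suppresses peaks greedily at normalized separation `2·gSig` (per-axis
normalization — with 3 µm planes an isotropic voxel window would merge
axially adjacent somata). Patch geometry (`rf` = 10, `stride` = 10) caps
seeds at `K` = 10 per patch.

Fitting is hierarchical alternating least squares: exact nonnegative 1D
updates for each trace and each footprint (restricted to a support box
that starts at side `4·gSig+1` around the seed, grows by `gSig` dilation
of the footprint's bounding box, and is confined to a window of side
`8·gSig+1` anchored at the seed), plus a rank-`nb` (= 2) background refit
of `Y − AC` by randomized SVD with a monotonicity guard. Every step is
non-increasing in `‖Y − AC − B‖²`; iteration stops at `n_iter` (30) or a
relative error change < 1e−4. After the first fit, a residual seeding
round seeds the correlation image of `Y − AC − B` and refits — somata
hidden behind a stronger neighbour at the first round reappear there.

Screening accepts components with peak SNR ≥ 1 — `(max − median)/σ` with
σ = 1.4826·MAD of the first-differenced trace / √2 — and footprint–image
Pearson correlation ≥ 0.5, computed against the movie averaged over the
trace's top-decile frames on the footprint's bounding box. The accepted
set seeds a full refit (the outer two-pass structure), near-duplicates
(overlapping footprints, trace r ≥ 0.8) are merged transitively with an
NNLS trace refit, and the screen is applied once more.

Because the trace-baseline × footprint direction is degenerate with the
static background, converged HALS footprints absorb static local
structure. The final spatial step resolves this the way the model intends
(static fluorescence belongs to `B`): each footprint is re-estimated by a
voxelwise nonnegative regression of the temporally mean-subtracted movie
on the baseline-subtracted trace, and weights below 4 standard errors of
the per-voxel noise are zeroed (expected false voxels per support window
< 1). Reported raw traces are the movie averaged over each footprint's
support; denoised traces are the constrained least-squares `C` — the
autoregressive order `p` = 2 is recorded but spike deconvolution is out of
scope.

## Post-filtering and connectivity

The volume filter keeps components with `voxels × voxel-volume` in
[710, 7605] µm³, bounds inclusive with 1e−9 relative tolerance (7605 µm³
is exactly 1500 voxels at the 20× geometry, so the ceiling is meant to be
attainable). The variance filter min–max-normalizes each trace and
discards variance > 0.06: a slow drift normalized to [0, 1] has variance
near 1/12 ≈ 0.083 while a sparse transient trace scores `p(1−p)` ≪ 0.06,
so high variance flags drift-dominated false positives; the direction is a
switch since either convention appears in practice. ΔF/F is provided as
`(F−Fmin)/(Fmax−Fmin)` (amplitudes homogenized) and `(F−Fmin)/Fmin`
(event-count sensitive).

Connectivity uses Spearman rank correlation (average ranks on ties) of
the raw traces — invariant under monotone amplitude distortions such as
illumination inhomogeneity — ordered by distance from the unweighted
centroid COM; a constant trace is rank-degenerate and its row/column is
zeroed with a warning. The graph keeps edges with `|R| > 0.8` strictly;
node degree is recomputed and stored for degree-coded display.

## Evaluation

Consensus annotation is the voxelwise AND of annotator masks. Voxel
precision/recall/F1 use the zero convention for empty denominators. For
synthetic scoring, weighted footprints (predicted *and* planted) are
binarized at 10% of each footprint's maximum — the planted ellipsoids'
rim voxels carry < 2% amplitude and are invisible to any estimator —
and components are matched to planted neurons greedily by descending
Jaccard overlap (threshold 0.1), deterministically tie-broken. At the
default benchmark (300 × 16 × 64 × 64, 20 neurons, seed 0) the pipeline
recovers 19/20 neurons, median matched-trace r = 0.979, voxel F1 = 0.617.

## Optics

All fitters are Levenberg–Marquardt nonlinear least squares with
moment-based initialization (offset = min, amplitude = max − min, centre =
argmax, width from the second moment), tolerances 1e−10, generous
iteration budget. The 2D Gaussian supports the rotated form (the usual
`a, b, c` rotation identities) and the axis-aligned `θ = 0` form used for
beam profiling. Beam-profile series fit `w(x) = 2σx(x)` with the
Gaussian-beam hyperbola; `xR = n π w0²/λ` with n defaulting to water
(1.33). PSF measurement detects beads as smoothed local maxima above
background, extracts the axis-aligned line profiles through each bead
centre — the stated lateral/axial profiles in the three central planes
collapse to three unique lines, each fit once — in physical coordinates
(anisotropic voxels are converted before fitting), and aggregates σ per
axis as mean ± sd over beads. Chromatic shift is the mean displacement of
intensity-weighted bead centroids matched between two stacks.

## Pipeline and problem sizes

`run_pipeline` executes reorder → bleach → Fourier filter → motion →
extraction → volume filter → variance filter → normalization → COM
ordering → Spearman → graph, writes every artifact plus a manifest with
per-stage SHA-256 checksums, and is bit-reproducible under a fixed seed
and configuration. Test and benchmark problem sizes (≤ 300 volumes of
64 × 64 × 16) are chosen so the full suite runs on a single CPU in a few
minutes; the algorithms are `O(T · N)` per iteration and scale to the
512 × 512 × 20 × 1000 recordings the configuration defaults describe.

## Known limitations

* Spike-train deconvolution is not implemented (denoised traces are
  constrained least-squares, not deconvolved).
* Piecewise-rigid motion correction is configuration-recorded only.
* The Fourier filter's benefit inverts at high signal-to-artifact ratio
  (see Preprocessing); it should be disabled for bright, artifact-free
  data.
* The synthetic benchmark does not model scattering tissue; real-data
  segmentation scores will be lower than the synthetic F1.
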