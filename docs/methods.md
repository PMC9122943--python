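# Methods

This note documents the models, estimators, parameters and numerical choices
behind `fixclust`, and what the synthetic-data tests do and do not
demonstrate about real data.

## AFM flattening

Raw height maps carry sample tilt, piezo bow and per-line offsets. The chain
is: (1) least-squares 2-D polynomial surface of total degree 2 (basis
1, x, y, x², xy, y² on coordinates normalised to [−1, 1] for conditioning),
subtracted; (2) per-fast-scan-row 1-D polynomial of degree 3, subtracted;
(3) 3×3 median filter with reflected edges. Steps 1–2 use robust trimming:
after an initial fit, pixels are ranked by |residual| and only the best
`tolerance` fraction (default 0.5) enters a single re-fit, so protrusions do
not drag the baseline upward. Plane fit precedes line levelling; the
fast-scan direction is assumed to be rows (a flag levels columns instead).
Heights are float64 nm throughout regardless of source bit depth. The chain
annihilates polynomial backgrounds up to its degrees exactly and is nearly
idempotent (second pass changes < 1% of the first-pass change).

## Half-maximum protrusion recognition

A protrusion is the region enclosed by the iso-contour at
`b + (z_peak − b)/2`, where `z_peak` is the peak height and `b` the local
background. Estimators:

- **Candidate peaks** are maxima with topographic prominence ≥
  `min_prominence` (h-maxima reconstruction). Plain 8-neighbour maxima are
  not sufficient: noise maxima riding on the flank of a tall protrusion pass
  a background-relative prominence test and would spawn spurious half-max
  fragments; reconstruction-based prominence suppresses them at the same
  parameter value.
- **Local background** `b` is the median height within a disk of radius
  `background_radius` (default 50 nm) around the peak. A rank statistic is
  unbiased under symmetric roughness; a morphological opening (the classic
  rolling-ball choice) is biased low by roughly 1–3 noise SDs, which shifts
  the half-max level and inflates areas by ~10% at 10:1 SNR. In crowded
  fields the disk median is biased slightly upward by neighbouring
  protrusions (a few percent of bump height at the default densities); this
  bias is common to all conditions being compared.
- **Peak apex** comes from a least-squares paraboloid over the 5×5
  neighbourhood (subpixel position and noise-averaged height), falling back
  to the pixel value at borders or non-concave fits.
- **Region claiming** is watershed-style: peaks processed in descending
  height flood-fill the connected region above their level that is not
  already claimed, so a saddle between two peaks splits at the
  claimed-region boundary.
- **Boundary and area**: subpixel marching-squares contour at the level
  (true heights everywhere except pixels claimed by higher peaks), area by
  the shoelace formula, centroid from the polygon. For an isotropic Gaussian
  bump of width σ the closed form is `2π ln2 σ²`; the detector reproduces it
  to ≤ 0.2% noiselessly and to ~2% on average at 10:1 white noise.
- **Optional smoothing**: with `smooth_sigma` > 0 detection runs on the
  Gaussian-smoothed surface and, by default, the kernel's own half-max area
  `2π ln2 σ_s²` is subtracted from reported areas — the usual "remove the
  blur in quadrature" correction, exact for Gaussian bumps. It is the
  recommended mode for noisy inputs (the acceptance checks use σ_s = 2 px).

Nearest distances between protrusions are centroid-to-centroid (matching
the fluorescence analysis, which measures centre-to-centre), computed with a
KD-tree that is exactly equivalent to exhaustive search.

**Persistence filtering.** Real surface features recur in consecutive
frames; scan artefacts do not. Global drift between consecutive topographs
is estimated by phase correlation (20× upsampled) and removed from centroid
coordinates; detections are then linked frame-to-frame by greedy
nearest-first bipartite matching under `max_disp` (default 10 nm, no gap
closing), and tracks spanning ≥ `k_min` frames (default 3) count as
persistent. On the synthetic drifting series (20 persistent bumps + 10
one-frame blobs, 2 nm/frame drift) the recovered count is 20 for every
tested seed.

**Statistics.** Condition comparisons use per-image mean areas/distances as
the statistical unit, compared with the Mann–Whitney U test: exact null
distribution when the pooled sample is ≤ 16 with no ties, otherwise the
normal approximation with tie and continuity corrections (scipy backend;
tests verify the exact branch against full enumeration).

## Hertz–Sneddon fitting

Model: `F(z) = F₀ + tilt·z` before contact and
`F(z) = F₀ + tilt·z + κ tanθ · E/(1−ν²) · (z₀−z)²` past the contact point
z₀, with face half-angle θ = 17.5°, front factor κ = 0.7453 (Bilodeau's
regular three-sided pyramid; κ = 1/√2 selects the four-sided convention —
fitted E scales inversely with κ tanθ, so the geometric convention is
explicit), and ν = 0.5 (incompressible cytoplasm). The linear baseline tilt
absorbs approach-baseline drift and can be disabled. Units: nm, nN, E in
kPa (1 nN/nm² = 10⁶ kPa).

Fitting is trust-region least squares over (E, z₀, F₀, tilt) with tight
tolerances (1e-14); initialisation takes the baseline level/noise from the
far 30% of samples, z₀ at the first point exceeding baseline + 3 SD, and E
from the closed-form inversion at the deepest point. Zero-noise forward
curves are inverted to ≤ 0.1% in all parameters; at 5% force noise the mean
recovered E over 200 replicates is biased < 1%. Only approach curves are
fitted. Adhesion, viscoelasticity and bottom-effect corrections are out of
scope.

## Fluorescence spot analysis

Spots are detected with a scale-normalised Laplacian-of-Gaussian at
σ = diameter/(2√2) (diameter default 0.5 μm). Quality is the negative LoG
response rescaled so an ideal Gaussian spot of matched diameter and unit
peak amplitude scores exactly 1.0 (a Gaussian filtered at its own σ has
centre response amplitude/2); the default threshold 0.2 is on this
normalised scale — a deliberate, documented recalibration of the
unnormalised threshold used by common trackers. Subpixel positions come
from quadratic refinement of the response peak.

Channel densities are equalised by trimming the denser channel to the
sparser channel's count, keeping the highest-quality spots; since both
channels share the crop region, this matches area-per-spot across channels
and makes the nearest-distance statistic comparable between conditions (a
flag disables it). Distances are measured A→B only (each A-spot to its
nearest B-spot centre) and averaged per cell; conditions are compared with
the two-sided equal-variance t-test on cell means (verified against the
textbook pooled-variance formula to 1e-9).

Time-lapse traces follow one A-spot by nearest-neighbour linking under
`max_disp`, recording its nearest-B distance per frame (2 s default
interval). Aggregation onset is the first time ≥ the fixation time at which
the distance stays below `low_threshold` (0.2 μm) for ≥ `hold` (3)
consecutive frames. In the simulated workflow the tracked molecule is chosen
among A-spots that end up aggregated with a B molecule, emulating the
experimenter's choice of a spot that visibly aggregates in the recorded
time-lapse; without that conditioning a quarter of traces never settle
because the spot aggregates only with its own species.

## Registration via membrane holes

The microporous support membrane provides a lattice of circular fiducials
(5 μm holes at 10 μm pitch; 3 μm variants exist) visible in both modalities
— dark in transmitted light/AFM height, bright after FITC staining
(polarity flag). Detection: Otsu threshold, connected components,
border-touching components discarded (clipped centroids are biased), keep
circularity `4πA/P² ≥ 0.8` and diameter within ±30% of expected; centres
are component centroids. Estimation: coarse alignment from each set's
lattice statistics (median NN spacing and NN-direction circular mean mod
90°), mutual-nearest-neighbour correspondences, closed-form least-squares
similarity fit (Umeyama, reflection-free), one re-matching refinement pass.
A perfectly regular lattice determines rotation only modulo 90°; ties are
broken toward the smallest rotation. On jittered lattices the transform is
recovered to ~0.01° / 0.001 scale / 0.01 μm. A similarity (not affine)
transform is used because the modalities differ by scale, rotation and
offset but not shear. Overlays are bilinear resampling with out-of-bounds
pixels masked as NaN.

## The fixation simulator

Two species of point particles (the two labelled, non-interacting membrane
proteins) diffuse in a 2-D box with reflecting walls — the membrane is
treated as a plane. Before `t_fix` no bonds can form, so the pre-fixation
segment advances by exact Brownian increments between recorded frames. From
`t_fix` the dynamics run at `dt`: any unbonded pair within the capture
radius bonds with probability `looseness` per step, permanently (the bond
list is append-only); clusters are connected components of bonds, move
rigidly, and their mobility follows the slowdown rule — default
`stokes_arrest`: D/n for an n-mer, multiplied by a linear ramp to zero over
`tau_arrest` = 10 s after the cluster's first bond, reproducing the ~10 s
settling seen in fixation time-lapses. `looseness` = 1 models crosslinking
aldehydes; 0.3 models the looser precipitation-driven aggregation of
methanol (fewer bonds at equal time, an ordering the tests assert); 0 is
the living control. A warning is raised if the step SD √(2D·dt) exceeds the
capture radius. Everything is bit-reproducible from (params, seed).

Default scales (chosen once, anchored to measured densities rather than
fitted to any outcome):

- **Fluorescence preset**: 200+200 particles in 16×16 μm, D = 0.01 μm²/s,
  dt = 0.05 s, capture radius 0.05 μm. The density gives a Poisson
  cross-channel nearest-distance mean of ~0.57 μm, the living-cell scale.
- **Topography preset**: 20+20 particles in 0.2×0.2 μm (protein
  nearest-neighbour spacing ~16 nm, the living-surface protrusion spacing),
  capture radius 5 nm (a protein diameter), dt = 1 ms so the step SD stays
  below the capture radius.

Renderers: clusters become isotropic Gaussian bumps (amplitude = monomer
height × members, capped at 5×, width σ·n^¼ — aggregates widen more than
they heighten, consistent with area being the robust readout) on correlated
roughness (RMS 0.2 nm, 5 nm correlation length) with per-line offsets and
per-frame drift; fluorescence channels are Gaussian PSFs (FWHM 0.25 μm
confocal, 0.06 μm STED) with fixed per-molecule brightness jitter and
shot-like noise; force curves are the forward Hertz model plus Gaussian
noise; hole lattices are soft-edged disks with optional centre/radius
jitter and a known transform between modalities.

## What the synthetic tests show — and what they do not

Passing tests demonstrate that the estimators are correct on data satisfying
their assumptions (Gaussian bumps, Gaussian PSFs, ideal Brownian sticking,
symmetric noise) and that the full pipeline reads out the fixation effect in
the right direction with calibrated magnitudes. They do not validate tip
convolution and feedback artefacts in real AFM, non-Gaussian PSFs or
labelling stochasticity, membrane topography coupling, protein anchoring to
cortex, or crosslinking chemistry kinetics; the aggregation in the
topographic preset is stronger than the modest (~2×) area growth seen on
real fixed cells, so condition contrasts on synthetic data should be read
as directional, not quantitative, predictions.

A statistical note on onset timing: under the bond-on-contact model a
tracked molecule's settling time is a first-passage (capture) time with
coefficient of variation ≳ 1. Its median lands in the 5–20 s window at the
default densities (the acceptance script reports it), but no
parameterization of a memoryless capture process can concentrate ≳ 50% of
individual replicates in that window — an intrinsic property of the model,
not an estimator deficiency.

## Problem sizes

The shipped studies use sizes chosen to keep the full suite quick on a
single core while leaving the statistical conclusions stable: 10–20 seeds
for estimator-law checks, 50–100 replicates for direction/onset statistics,
200 replicates for Hertz bias, 15–30 images/cells for condition
comparisons. All are parameters of the public workflow functions.
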