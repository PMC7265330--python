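# Methods

## Overview

`kinetocoloc` quantifies recruitment of a fluorescently tagged protein to
kinetochores in two-channel 3D time-lapse microscopy. The biological
setting is the spindle assembly checkpoint in human RPE cells: a
kinetochore marker channel (RFP670-MIS12-like) shows ~46 diffraction-
limited spots inside the nucleus, and a signal channel (Ruby-MAD2-like)
shows a diffuse nucleoplasmic pool from which a growing fraction
relocates to kinetochores around nuclear envelope breakdown (NEBD). The
package also implements two fixed-cell colocalization statistics and
NEBD-normalized fluorescence kinetics, and ships a synthetic-movie
generator with exact ground truth so the whole pipeline is testable
without microscope data.

## The 3D+T colocalization statistic

For each frame, each channel volume is

1. **resliced in z to isotropic sampling** at the finest existing voxel
   pitch (node-aligned linear interpolation; nearest-neighbour
   selectable; a single-slice stack falls back to nearest with a
   warning),
2. **smoothed** with an isotropic Gaussian, σ = 1 voxel, reflective
   boundaries,
3. the marker channel is **thresholded** at 1.08 × the Otsu threshold of
   the full-volume 256-bin histogram (the fixed 1.08 scale makes the
   segmentation slightly conservative while remaining invariant to
   uniform intensity rescaling),
4. speckle is removed by **morphological opening** with a cubic
   structuring element of side 3 (radius 1 voxel); connected components
   are counted with 26-connectivity.

The statistic is then

```
coloc(t) = mean(signal | spot mask) / mean(signal | background shell)
```

where the background shell is every voxel inside the nucleus, outside
the spots, whose Euclidean distance to the nearest spot voxel lies in
[1, 15] voxels (Chebyshev distance selectable). A value of 1 means the
signal at kinetochores matches the nucleoplasmic pool; R means R-fold
enrichment. Frame k is reported at t = (k − NEBD frame) × frame interval
(minutes); NEBD is always a user input, never detected. Frames with an
empty mask or shell carry NaN and a flag, and post-NEBD frames are
flagged because the nucleus-mask heuristic below is, strictly, a
pre-NEBD construct even though traces continue past NEBD.

### Nucleus mask

How "the rest of the nucleus" is delimited is a genuinely open design
point; the package derives it from the signal channel itself: smooth
heavily (σ = 5 voxels) so spots wash into the pool, Otsu-threshold, fill
holes, keep the largest 26-connected component, then **erode by 3
voxels**. The erosion matters: the smoothed intensity rolls off over a
few voxels at the nuclear envelope, and without erosion those dim rim
voxels enter the shell and inflate a flat-field ratio by ~9–15%
(measured on synthetic movies); with the 3-voxel erosion a flat signal
yields 1.00 ± 0.01. A caller with a dedicated nuclear marker can pass
precomputed masks and bypass the heuristic. All of `smooth_sigma`,
`otsu_scale`, `opening_radius`, `shell_dmin/dmax`, `nucleus_sigma`,
`nucleus_erosion` live on `ColocParams`.

`"kernel = 1 voxel cube"` for the opening is interpreted as a cube of
*radius* 1 voxel (side 3): a side-1 cube is the identity and removes no
noise. `opening_radius=0` selects the literal side-1 reading.

Cross-cell aggregation bins per-cell traces onto the shared
NEBD-relative lattice (no interpolation across cells) and reports mean
and SEM (sample SD/√n); SEM is reported missing when fewer than two
cells contribute at a time point.

## Synthetic movies

The generator emulates the imaging regime rather than the optics:

- **Geometry** — a spherical nucleus (default radius 6 µm) in a
  (32, 96, 96)-voxel volume at 0.25 µm xy / 0.5 µm z pitch (z ≥ xy
  enforced). 46 spots are placed uniformly at random inside the nucleus
  eroded by 2 spot-σ, with a minimum center-to-center distance of
  2.0 µm. The separation default is deliberately larger than a few
  spot-σ: after the mandated σ = 1 voxel smoothing, spots ~1 µm apart
  merge into single connected components above threshold, which would
  make spot-count ground truth meaningless. Centers are static by
  default (`motion_sd` adds an optional random walk); per-frame
  quantification does not depend on motion.
- **Spots** — isotropic-in-physical-units Gaussians, σ = 0.3 µm, unit
  peak; no further point-spread-function modelling, chromatic
  aberration, or photobleaching.
- **Marker channel** — dim nuclear background (0.01) plus unit-amplitude
  spots.
- **Signal channel** — uniform nuclear baseline B = 0.5 plus the same
  spot profile with a per-frame amplitude A(t) chosen so that the
  noise-free spot-mean/shell-mean ratio **exactly** equals the ground
  truth 1 + f(t)(R − 1), where f(t) = fmax/(1 + exp(−(t − t50)/τ)) is
  the recruited fraction and R the enrichment ratio at full recruitment
  (defaults fmax = 0.8, t50 = −10 min, τ = 2 min, R = 3, 2-min frames).
  The calibration runs the reference segmentation (default
  `ColocParams`, including the derived-nucleus heuristic) once on the
  noise-free marker, measures the mean of the unit spot field and of the
  nucleus indicator over the resulting mask and shell after the same
  reslice-and-smooth chain, and solves
  `(B·u_spot + A·m_spot) / (B·u_shell + A·m_shell) = 1 + f(R−1)` for A.
  The ground truth is therefore *operational*: it is defined with
  respect to the same measurement geometry the analysis uses, which is
  what makes "parameter recovery within x%" a sharp statement. With
  f = 0 the amplitude is exactly 0 (no spot excess).
- **Noise** — Poisson shot noise at `photon_scale` counts per intensity
  unit plus additive Gaussian read noise, the standard sCMOS
  approximation: `Poisson(photon_scale·µ)/photon_scale + N(0, σ_read)`,
  clipped at 0. Defaults (photon_scale 200, σ_read 0.005) give a peak
  SNR of ~14 on the marker. No intensity calibration exists to match;
  the defaults are stated here and in `SyntheticParams`, not inferred
  from any figure.
- **Determinism** — one `numpy` Generator seeded from `params.seed`
  drives placement, noise, and motion; identical parameters give
  bit-identical movies.

What the generator does **not** emulate: cell movement and deformation,
nuclear envelope breakdown itself (the nucleus stays intact at all
frames), spot-to-spot intensity variability, uneven illumination, and
anisotropic PSF tails. Passing tests therefore demonstrate correctness
of the measurement chain under the stated image-formation model, not
robustness to every property of real movies.

## Fixed-cell statistics

**Auto-thresholded colocalization percentage** (2D, maximum projection,
ROI defaulting to 4.2 µm²): ordinary least squares fits b ≈ m·a + c over
the ROI; candidate pairs (T, m·T + c) are swept downward from max(a) in
256 steps; the chosen pair is the highest whose below-both-thresholds
pixel population has Pearson correlation ≤ 0 (candidates whose
below-threshold set is too small or degenerate cannot be certified and
are skipped; if no candidate qualifies — e.g. identical channels — the
sweep floor is returned and flagged). The percentage is then
100 × |a > Tₐ ∧ b > T_b| / |a > Tₐ|: the fraction of above-threshold
*reference*-channel pixels that colocalize (a thresholded Manders-style
fraction). Because plugin-style "percentage colocalization" is
ambiguous, the alternative convention (divide by all ROI pixels) is
selectable via `denominator="roi_total"`, and the convention used is
recorded in the result.

**Profile overlap percentage** (1D, default 6-µm line ROI at the nuclear
envelope): 100 × ∫min(a, b) dx / ∫a dx with trapezoidal integration —
the area of the reference profile (TPR-like channel) covered by the
second profile. Asymmetric by design. Each profile's minimum is
subtracted as baseline by default (clipped at 0); disable with
`subtract_baseline=False`.

## Kinetics and statistics

`normalize_to_nebd` divides a per-cell fluorescence series by its value
at the NEBD frame (exactly 1 at t = 0, scale-invariant, idempotent);
`mean_trace` averages cells per time point with sample SD.
`mann_whitney_u` returns the U statistic (pairs with x > y, ties ½) and
a two-tailed p: for n·m ≤ 400 without ties, the exact null distribution
is built by the standard removal recurrence and p = min(1, 2·min(P(U′ ≤
U), P(U′ ≥ U))); with ties or larger samples, a normal approximation
with midrank tie correction and continuity correction is used (ties
forbid the exact branch because the null is no longer
distribution-free).

## Numerical choices

- Reslicing is node-aligned: output sample k sits at physical position
  k·target along each axis, so an axis with n samples at pitch d maps to
  round((n−1)·d/target)+1 samples and the physical extent is preserved
  within one voxel. Coordinates are clipped against round-off at the far
  edge.
- Images are promoted to floating point on load; generated movies are
  float32.
- Otsu uses the full-volume histogram (not restricted to the nucleus),
  256 bins; a constant volume raises a degenerate-histogram error. The
  implementation delegates to scikit-image; tests hold it to an
  exhaustive intraclass-variance minimizer.
- Opening treats out-of-volume voxels as background.
- Trace aggregation matches times after rounding to 9 decimals; SEM uses
  ddof = 1.
- Spot placement is rejection sampling with a 200 000-attempt cap; an
  over-packed request fails loudly with a degenerate-geometry error.

## Problem sizes used in validation

The validation suite and the reproduction script run at the study
conditions — 46 spots, SNR ≈ 14, (32, 96, 96)-voxel frames — with 20
movies per enrichment ratio R ∈ {1, 2, 3, 5} held at the recruitment
plateau (2 frames each), three 12-frame movies spanning the recruitment
onset for the rank-correlation check, and two 20-cell cohorts of
11-frame movies (half-recruitment at −10 vs 0 min) for the onset
contrast. Measured behaviour at these sizes: mean recovered plateau
within ~2% of 1 + f(R−1) for every R; Spearman rank correlation with the
true recruited fraction > 0.95; early-onset cohort above the late-onset
cohort by ≥ 2 combined SEM at every pre-NEBD time point once recruitment
begins.

## Known limitations

- The shell is computed in 3D on the isotropic grid; a per-slice 2D
  variant is not offered.
- No sub-voxel spot localization, per-kinetochore tracking, or watershed
  splitting of touching spots — the statistic pools all spot voxels.
- The nucleus heuristic assumes the signal channel has a visible diffuse
  nuclear pool; for a signal protein with no nucleoplasmic fraction a
  user-supplied nucleus mask is required.
- The exact Mann–Whitney branch refuses ties; Prism-style exact
  mid-p conventions are not implemented.
- OME-TIFF support covers axes that are subsets of TCZYX with
  PhysicalSize/TimeIncrement metadata; proprietary microscope formats
  are out of scope.
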