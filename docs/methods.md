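# Methods

This note records the modelling conventions, numerical choices and known
limits of the package — the decisions a maintainer or reviewer would want
spelled out.

## Phase reconstruction

**Sideband demodulation.** The carrier is located as the largest spectral
peak outside a DC-exclusion disc of 4 frequency bins, searched in the
positive-column-frequency half-plane (the conjugate lobe carries the negated
phase; generators and instruments here use positive carriers). Detection
requires the peak to exceed 3× the median off-DC magnitude, otherwise a
carrier-detection error names the measured spectral SNR. The bandpass is a
circular mask of radius `radius_fraction` × (carrier distance), default 0.5 —
the largest radius that can never reach the DC term. The selected lobe is
re-centered by an integer-bin roll; sub-bin carrier error therefore leaves a
small residual tilt, which the later plane fit removes. All transforms run at
the native frame size, without zero-padding.

**Unwrapping.** Unweighted least-squares unwrapping (Ghiglia–Romero):
wrapped first differences are assembled into the discrete Laplacian and the
Poisson equation is solved under Neumann boundary conditions with the
orthonormal type-II DCT. The solution is exact (RMS < 1e-6 rad; measured
~1e-12) whenever the true per-pixel gradient magnitude stays below π. The
free additive constant is fixed so the minimum over the frame border is zero.

**Background flattening.** A least-squares plane is fitted to background
pixels — the complement of a supplied cell mask, or the 25% lowest-phase
pixels when no mask is given — and subtracted; the background median is then
shifted to exactly zero. Reference-beam curvature beyond a plane is not
modelled.

With a noise-free phantom, the full chain (hologram → sideband → unwrap →
flatten) recovers the generating phase with in-mask RMS ≈ 0.02 rad; the
residual is bandpass ringing concentrated at the cell rim, where the
Evans–Fung thickness has a sqrt-shaped edge.

## Segmentation

Foreground is thresholded (Otsu, or a fixed level in radians), then
hole-filled — a doughnut-shaped cell whose dimple drops below threshold must
segment as one instance, not an annulus. Touching cells are split by a
watershed on the negated Euclidean distance transform seeded from its
h-maxima, with marker depth h = 3 px: small enough to seed every cell of
radius ≳ 15 px, large enough to absorb boundary-digitisation ripples in the
distance ridge. Components below `min_area_um2` (default 10 µm², far below
any RBC's ~45 µm² projection) are discarded and labels renumbered 1..N.
Instance matching for evaluation is greedy one-to-one in descending IoU with
threshold 0.5; "mean IoU" averages over matched pairs.

For volume-accurate downstream measurement a low fixed threshold
(~0.08–0.1 rad) is preferable to Otsu: Otsu places the cut partway up the
cell's phase skirt and clips 2–3% of the optical volume, while a low fixed
threshold on a flattened map loses only the sub-noise tail.

## The 15 features

* **Phase statistics** are computed over in-mask pixels only. Optical volume
  carries the pixel area (rad·µm², i.e. magnification-invariant); divide by
  `pixel_size**2` to recover the plain phase sum. Percentiles use linear
  interpolation between order statistics; the SD is the population SD — a
  per-cell descriptor, not an estimator.
* **Morphology**: area = pixel count × pixel area; perimeter = total
  marching-squares contour length on a Gaussian-smoothed (σ = 1 px) copy of
  the mask, which removes the digitisation bias of contouring a hard binary
  edge (disc phantom error ~0.4% vs ~7% unsmoothed); axes from the
  moment-matched ellipse (4·√eigenvalue); eccentricity = √(1 − (b/a)²).
* **GLCM texture**: in-mask phase linearly quantised to 32 levels between the
  in-mask min and max; co-occurrences counted only for pixel pairs both
  inside the mask, at distance 1 px for the four standard offsets,
  symmetrised and normalised per offset. Contrast, dissimilarity, homogeneity
  and ASM are averaged over offsets; energy is defined as √(averaged ASM), so
  energy² ≡ ASM exactly. A constant cell returns (0, 0, 1, 1, 1).

Cells touching the frame border are excluded from feature tables (their
statistics would be truncated); the count is logged.

Because the quantisation is per-cell min–max, GLCM features are invariant to
any affine rescaling of the phase — they measure the *normalised* spatial
structure. One consequence matters for interpretation: for a smooth,
noise-free height field they reduce to a deterministic function of cell shape
and size, and therefore correlate with class in any phantom whose classes
differ in shape. See "Synthetic cohort" below.

## 3-D morphology

Thickness is recovered as T = λφ/(2πΔn) under the constant-RI assumption,
clipped at zero. Volume is the thickness integral. Surface area models the
cell as mirror-symmetric about its midplane: S = 2·Σ √(1 + |∇(T/2)|²) dA over
the mask with central-difference gradients; there is no explicit rim term
because the phantom thickness vanishes at the support edge. The Evans–Fung
profile has a sqrt cusp there, so S converges as √(pixel size) — volume is
insensitive (<0.1% at any tested scale) while S needs ~0.02 µm/px for
sub-percent discretisation error.

Profile features use the mask centroid and the equivalent-disc radius
R_eq = √(area/π). T₀ is the mean thickness within ρ ≤ 0.1 (a small central
average rather than a single-pixel read, for noise robustness; its analytic
counterpart uses the same convention). T̄(0.75) averages 64 bilinear samples
on the circle ρ = 0.75, and Δ75 = T̄(0.75) − T₀, positive for doughnuts. The
Δn used for phase→thickness conversion is a configuration value (default
0.06), not a measured constant.

## Classifier and attribution

XGBoost binary classifier (depth 3, 200 rounds, learning rate 0.1, logistic
loss, single thread, seeded; thalassemic = positive class at threshold 0.5).
Dataset splits are *grouped*: all augmented copies of one physical cell carry
its `cell_id` and land in the same partition, so rotation-augmented
near-duplicates can never leak across a 4:1 split. AUC is the Mann–Whitney
rank statistic over predicted scores.

Shapley values are exact: all 2^M coalitions are enumerated (M = 15 →
32,768), with the coalition value defined as the interventional marginal
expectation over an explicit background sample (default 25–100 seeded
training rows). Attributions are in margin (log-odds) units and satisfy
efficiency to float accuracy; the implementation is cross-checked in the test
suite against a literal double-loop enumeration. Global importance is the
mean |attribution| per feature, ties broken by feature name.

With strongly correlated informative features, boosted trees concentrate
their splits on one representative per correlated cluster, and interventional
Shapley assigns near-zero credit to the unused substitutes. Feature-importance
conclusions are therefore stated at group level (phase statistics vs
morphology vs texture), which is robust; the exact rank order *within* the
correlated clusters below the top features is not a stable quantity and is
not asserted anywhere.

## Canonical correlation analysis

Columns are standardised to zero mean and unit *population* variance
(divisor n, consistently with the covariance convention). The solver whitens:
K = Sxx^(−1/2) Sxy Syy^(−1/2) via symmetric inverse square roots
(eigendecomposition; ridge 1e-8 with a warning if a within-set covariance is
numerically singular), and the SVD of K gives the canonical correlations and
coefficients; k = min(p, q) pairs. Variates have unit variance and are
mutually uncorrelated within a set. Within-set loadings are plain Pearson
correlations between each original variable and its own set's variates.
Each pair's sign is fixed so the x-variable with the largest |loading| loads
positively — canonical pairs are only identified up to a global sign flip, so
loading *patterns* are comparable but individual signs are conventions.
Requires n > p + q.

## Synthetic cohort (what the generator emulates, and what it does not)

`sample_population` draws Evans–Fung parameters per cell from Gaussian class
priors (units µm except Δn):

| parameter | healthy | thalassemic |
|---|---|---|
| radius R | 3.85 ± 0.35 | 3.55 ± 0.35 |
| c₀ (center thickness) | 0.75 ± 0.20 | 0.15 ± 0.06 |
| c₂ | 7.8 ± 0.7 | 10.6 ± 0.7 |
| c₄ | −4.4 ± 0.45 | −6.6 ± 0.5 |
| Δn | 0.0630 ± 0.0035 | 0.0540 ± 0.0035 |

Draws with a negative thickness polynomial (or degenerate radius/contrast)
are rejected and resampled. These priors encode mild microcytosis (smaller,
overlapping radii), hypochromia (lower Δn) and a much deeper relative dimple
for the thalassemic class. At the defaults the cohort reproduces, with wide
margins over a 10-seed sweep, the qualitative disease signatures: lower
optical volume, mean and 5th-percentile phase but higher phase SD for
thalassemic cells; higher Δ75 and S/V and lower sphericity (doughnut trend);
a first canonical pair dominated by OV↔V and a second pair linking phase-SD
positively to S/V and Δ75 and negatively to sphericity.

Per-cell 2-D feature images additionally carry two acquisition effects
(`apply_imaging_effects`): an additive speckle-like coherent-noise field
(correlation length 1.2 px, per-acquisition amplitude uniform in
0.02–0.09 rad) and focus jitter (Gaussian blur, σ uniform in 0.2–0.9 px).
Both vary far more between acquisitions than between classes, which is what
makes texture descriptors unreliable in practice; 3-D features are computed
from the ground-truth thickness, emulating the separate tomographic modality.
The hologram forward model is thin-object: I = I₀|1 + m·e^{i(φ+2πf·r)}|² with
seeded Gaussian camera noise, clipping and 16-bit quantisation; phases of
touching cells superpose.

Not emulated: physical diffraction and defocus of the optical system, camera
MTF, intracellular haemoglobin granularity as a resolved structure,
subject-level (per-patient) correlation structure, and cell-shape asymmetry
(the family is axisymmetric, so eccentricity carries no class signal).
Passing tests on this cohort demonstrate that the pipeline measures what it
claims on objects with known ground truth and reproduces the documented
population contrasts — not that the classifier's absolute accuracy would
transfer to clinical data.

## Problem sizes

Default scales, chosen so the full demo pipeline runs in minutes on one core:
populations of 400 cells per class at 0.1 µm/px on per-cell grids; scenes of
~6 cells on 512² canvases at carrier (0.25, 0.25) cycles/px; Shapley
attribution on 12–16 instances against 25 background rows (≈13M model
evaluations); CCA oracle checks on 50 random (n = 500, p = 4, q = 6) problems
plus one planted-factor problem at n = 10,000.
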