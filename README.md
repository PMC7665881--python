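# qpirbc

Quantitative phase imaging (QPI) pipeline for red blood cells (RBCs):
off-axis hologram reconstruction, single-cell segmentation, a 15-feature
morphometric/texture quantification scheme, gradient-boosted classification of
thalassemic vs healthy cells with exact Shapley attribution, and canonical
correlation of 2-D phase statistics against 3-D cell morphology. A parametric
phantom generator makes every stage testable without any external data.

## Who this is for

QPI / digital holographic microscopy (DHM) practitioners who want a
transparent, classical reference pipeline for label-free RBC analysis: from a
raw off-axis interferogram to per-cell biophysical features and an
interpretable classifier. Thalassemia-minor RBCs are hypochromic (lower
haemoglobin, hence lower refractive-index contrast Δn) and trend toward flat,
doughnut-like shapes; both effects are visible in the phase image.

## The science in brief

A transparent cell imposes a phase delay φ(x,y) = (2π/λ)·Δn·T(x,y) on
transmitted light, where T is local thickness and Δn the refractive-index
contrast (nearly constant inside an RBC). An off-axis DHM encodes the complex
field on a spatial carrier; reconstruction is

1. **Sideband demodulation** — bandpass the spectral lobe at the carrier,
   re-center it at DC, inverse FFT (no zero-padding);
2. **Phase unwrapping** — unweighted least-squares (Ghiglia–Romero): wrapped
   first differences → discrete Laplacian → Poisson solve under Neumann
   boundary conditions via the type-II DCT;
3. **Background flattening** — plane fit over background pixels.

Per segmented cell, 15 features are extracted (Haralick texture from a
masked, symmetric, 32-level gray-level co-occurrence matrix):

| group | features |
|---|---|
| phase statistics | optical volume OV = ∫φ dA, φ_mean, φ_P5, φ_P95, φ_SD |
| 2-D morphology | area, perimeter, major/minor axis, eccentricity |
| GLCM texture | contrast, dissimilarity, homogeneity, energy, ASM |

An XGBoost classifier separates the classes; per-feature influence is
quantified by **exact Shapley values** (full 2^15-coalition enumeration of the
interventional marginal expectation — no sampling approximation), ranked by
mean |value|. Finally, **canonical correlation analysis** (SVD of the whitened
cross-covariance) relates X = (OV, φ_mean, φ_P5, φ_SD) to six 3-D features
computed from thickness maps: volume V, S/V, sphericity index
SI = π^(1/3)(6V)^(2/3)/S, T_avg, T_0, and Δ75 (thickness at 3/4 normalized
radius minus central thickness; positive for doughnuts).

Phantoms use the Evans–Fung biconcave parameterization
T(ρ) = √(1−ρ²)(c₀ + c₂ρ² + c₄ρ⁴), which has closed-form volume and profile
values, so every measurement is validated against analytic ground truth.

## Worked example

Forward-model the classic discocyte (R = 3.91 µm, coefficients
(0.81, 7.83, −4.39) µm, Δn = 0.06 at λ = 532 nm), then run the full
measurement chain:

```python
from qpirbc import (PhantomSpec, discocyte_thickness, phase_forward,
                    hologram_forward, reconstruct_phase, segment_cells,
                    extract_features, thickness_from_phase, cell_features3d)

spec = PhantomSpec("healthy", radius=3.91, shape_coeffs=(0.81, 7.83, -4.39),
                   delta_n=0.06, wavelength=0.532)
t = discocyte_thickness(spec, (256, 256), pixel_size=0.08, center_px=(128, 128))
phase = phase_forward(t, spec.delta_n, spec.wavelength)
holo = hologram_forward(phase, carrier=(0.25, 0.25), noise_sd=0.0)

rec = reconstruct_phase(holo)                      # sideband -> unwrap -> flatten
labels = segment_cells(rec, threshold_method="fixed", fixed_threshold=0.08)
table = extract_features(rec, labels)
print(table[["ov_rad_um2", "phase_mean_rad", "phase_sd_rad", "area_um2"]])

thick = thickness_from_phase(rec, labels.labels == 1, spec.delta_n, 0.532)
print(cell_features3d(thick))
```

Output:

```
 ov_rad_um2  phase_mean_rad  phase_sd_rad  area_um2
     66.822           1.351         0.456    49.466
{'volume_um3': 94.297, 'surface_um2': 132.14, 'sv_ratio_per_um': 1.401,
 'sphericity': 0.758, 't_avg_um': 1.906, 't_0_um': 0.839, 'delta_75_um': 1.677}
```

The recovered volume (94.3 µm³) matches the phantom's closed-form volume of
94.1 µm³ to 0.2%; the optical volume 66.8 rad·µm² equals (2πΔn/λ)·V as the
constant-RI model predicts; and the positive Δ75 = 1.68 µm reflects the
biconcave dimple.

## Command line

Each stage is also a subcommand:

```bash
qpirbc simulate    --out scene/ --n-cells 6 --seed 7
qpirbc reconstruct --input scene/hologram.tif --output phase.tif
qpirbc segment     --phase phase.tif --out labels.tif --method otsu
qpirbc features    --phase phase.tif --labels labels.tif --out features.csv
qpirbc features3d  --phase phase.tif --labels labels.tif --delta-n 0.06 --out f3d.csv
qpirbc train       --features features.csv --split 4:1 --seed 7 --out model/
qpirbc explain     --model model/ --features test.csv --background train.csv
qpirbc cca         --x f.csv --x-cols ov_rad_um2,phase_mean_rad,phase_p5_rad,phase_sd_rad \
                   --y f.csv --y-cols volume_um3,sv_ratio_per_um,sphericity,t_avg_um,t_0_um,delta_75_um \
                   --out cca.json
qpirbc run         --out run/ --seed 7      # the whole pipeline
```

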