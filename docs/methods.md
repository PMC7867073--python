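# Methods

## Forward model of the synthetic test bed

Synthetic spectra are additive Beer–Lambert mixtures,
A(λ) = b·Σ_j ε_j(λ)·(1 + k_j·(T − 20))·s_j(S)·C_j, over a 0.4 nm pixel grid
(b = 10 mm path). The component set follows a standard artificial-seawater
recipe — NaCl 0.55 mol/L, MgSO₄ 28 mmol/L, NaHCO₃ 2.3 mmol/L, NaBr
0.8 mmol/L, sodium humate 5 µmol/L, NaH₂PO₄ 2.26 µmol/L, NaNO₂ 0.22 µmol/L —
plus nitrate at the requested concentration. Sea-salt species (chloride,
sulfate, bicarbonate, bromide) scale with salinity as s_j = S/35; nutrients
and humate do not. Only bromide carries a temperature coefficient
(k = +0.006 per °C about 20 °C, linearized), reproducing the qualitative
behaviour that LNS and bromide absorbance rise with temperature while
nitrate does not.

The extinction shapes are fixed, versioned constants chosen for qualitative
realism, not measured seawater optics: chloride is a steep exponential edge
dominating below 208 nm, bromide an exponential decay over 200–240 nm,
nitrate a Gaussian band centred at 202 nm (σ = 10 nm) clamped to zero at
λ ≥ 240 nm, and CDOM an exponential tail exp(−s(λ − 240)) with spectral
slope s = 0.015 nm⁻¹ (a linear CDOM variant is available; it makes the
baseline correction exact and is useful in tests). Noise is zero-mean
Gaussian per pixel with σ obtained by first-order propagation of intensity
noise through A = −log₁₀(I/I₀) at A = 0: σ = √2·(1/SNR + n_d/I₀)/ln 10
≈ 6.4×10⁻⁴ AU for SNR = 1000:1, dark noise n_d = 2.5 counts and a
60 000-count reference level. The √2 accounts for noise on both beams; the
A = 0 linearization means σ does not grow with sample absorbance, which
real detectors would show at high attenuation.

What the generator deliberately omits: lamp drift, stray light, wavelength
shifts, turbidity/particulates, depth/pressure effects, sample aging, and
any nonlinearity of the spectra in concentration (superposition holds to
1e-12 by construction). Tests passing on this bed therefore demonstrate
algorithmic correctness and noise robustness, not instrument-level
validity.

## Temperature/salinity correction

The correction assumes (i) sea-salt absorbance is proportional to salinity,
(ii) its temperature dependence is smooth, and (iii) nitrate does not
absorb beyond 240 nm so the 240–260 nm residual is pure baseline.

From a zero-nutrient calibration sweep (default 4–25 °C at 1 °C steps,
salinity-normalized to 35 psu) two objects are fitted:

- the **LNS surface**: a bivariate polynomial in centered/scaled wavelength
  and temperature, default degrees (3, 2) — the lowest degrees that track
  the curved absorbance surface on a 22-temperature grid while keeping the
  design well conditioned. It provides the diagnostics (R², RMSE, SSE) and
  a portable smooth summary. On the synthetic bed its R² is ≈ 0.94: a
  cubic in wavelength under-fits the exponential chloride/bromide edge.
  This is cosmetic, because
- the **sea-salt absorptivity grid** E(λ, T) used for the actual
  subtraction is fitted per calibration pixel as a polynomial in normalized
  temperature (degree = the surface's temperature degree, default 2).
  Per-pixel fitting is exact for any smooth temperature law at every
  measured wavelength, which is why the chain zeroes nitrate-free spectra
  to machine precision at arbitrary temperatures.

Per sample: A_ss(λ) = E(λ, T)·S is subtracted from the raw (unnormalized)
absorbance, a straight line fitted by OLS on the 240–260 nm residual (raw
nm coordinates; coefficients (e, f) are returned) is extrapolated over and
subtracted from 208–240 nm, and the window is restricted. Negative
corrected absorbances are preserved — clipping would bias the regression.
The per-psu absorptivity-transfer ratio (measured/model) is exposed as
`molar_absorptivity` for drift scenarios but is unity inside `apply_tsc`,
since calibration and measurement share one instrument; applying it
elementwise per sample would be circular (it subtracts the nitrate signal
with everything else). With an exponential CDOM tail the linear baseline
is an approximation; because the tail's curvature is shared across samples
it shifts all corrected spectra by a common shape that the regression
intercept absorbs.

## Kernel PLS and the ensemble

Components are extracted by NIPALS in kernel space with two-sided deflation
of K and Y-deflation by the score outer product. Numerical choices: the
score iteration starts from the first column of the current Y residual
(deterministic; a seeded random start is available), tolerance 1e-10 on the
score change, 500 iterations maximum (single-response fits converge in one
pass), non-convergence is a warning, and a collapsed (zero-norm) score
aborts with an error naming the component. Y is mean-centered inside the
fit and the mean restored at prediction. The dual coefficients use the
original (un-deflated) centered kernel in TᵀKU, the convention of the
kernel-PLS literature; with a linear kernel predictions match classical
PLS to better than 1e-6 (verified against an independent implementation).
Kernel centering uses the standard feature-space formulas for train and
test kernels.

Kernels: linear and rbf. The rbf width defaults to the median heuristic
γ = 1/median(pairwise squared distances), resolved once on the full
training set and recorded in the model so all ensemble sub-models share
one feature space. The component count can be fixed (default 12 in the
workflows) or selected as the smallest count whose training R² reaches
0.9995; on the synthetic bed that rule selects ~4 components and leaves
several-fold larger errors, so the fixed default is used for the
benchmark.

The ensemble fits D = 20 sub-models on random η = 80% subsets drawn without
replacement (η, D configurable; they are conventions, not fitted values),
weights them by inverse RMSEP evaluated on the full training set (an
out-of-bag option scores each sub-model on its held-out complement), and
floors zero RMSEPs at 1e-12 before inversion. Weights are positive and sum
to one; the prediction is a convex combination of sub-model predictions.
In an overfit-prone regime (small n, many components, noisy targets) the
ensemble beats a single full-data fit in the large majority of seeded
repetitions.

## Comparators

TSC-MLR is OLS (with intercept) on the identical corrected 208–240 nm
input, so the comparison isolates the regressor; rank-deficient designs
fall back to the minimum-norm solution with a warning. The ISUS-style
retrieval solves, per sample over 217–240 nm, a three-parameter linear
least-squares decomposition into the empirical seawater exponential
(parameters A = 1.1500276, B = 0.02840, C = −0.3101349, D = 0.001222;
W = λ − 210 nm) scaled by S/35 (salinity fixed from the sensor, not free),
the nitrate extinction spectrum, and an affine baseline. It is exact on
data generated from its own model family. On the synthetic bed its errors
are large even after the final linear recalibration: the empirical
seawater term differs from the synthetic matrix in both magnitude and
temperature slope, and a single global affine correction cannot remove a
temperature-dependent bias. This mirrors the known fragility of
transferring instrument-specific seawater models.

## Workflow problem sizes and defaults

The benchmark uses 600 training and 200 test samples, nitrate uniform on
0–100 µmol/L, T on 4–25 °C, S on 30–35 psu, SNR-1000:1 noise on samples and
calibration sweep alike, a 200–280 nm working grid at 0.4 nm (covering the
modeling and CDOM windows with margin), rbf kernel, 12 components, η = 80,
D = 20. The extrapolation study trains on 300 in-band samples and predicts
100 samples per out-of-range band, reporting the ±2 µmol/L fraction.
Every random draw derives from a single seed via spawned generator
streams, so runs are bit-reproducible.

Under these conditions TSC-WA-KPLS and TSC-MLR both reach ≈ 0.05 µmol/L
test RMSEP — the spectra–concentration map of the synthetic bed is exactly
linear, so OLS is near-efficient and the two methods are statistically
tied (the rbf kernel costs a few thousandths of a µmol/L of approximation
error). The advantage of the kernel ensemble on real spectra comes from
nonlinearities (broadband-source effects, matrix interactions) that the
linear generator intentionally does not contain; the benchmark therefore
checks accuracy, residual–temperature independence, and the
interpolation/extrapolation contrast, rather than a method ranking the bed
cannot express.

## Known limitations

- Extinction shapes and the bromide temperature slope are plausible
  stand-ins; absolute absorbances and the LNS-surface R² are not
  comparable to measurements on real seawater.
- Constant-σ noise understates error at strongly absorbing pixels.
- The CDOM correction assumes a sample-independent spectral slope; varying
  CDOM composition would leave sample-specific baseline residuals.
- No turbidity correction; spectra are assumed filtered.
- The kernel model cannot extrapolate: more than ~10 µmol/L above the
  training range, predictions fail entirely (this is a documented property,
  not a defect).
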