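# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of the `arexcest` quantification chain.

## Signal model

All z-spectra are dimensionless fractions `Z(Δω) = S(Δω)/S0` with Δω the
saturation offset in ppm from water. The labelled spectrum is modelled as a
baseline minus Lorentzian saturation pools,

    Z(Δω) = Z_base − Σ_i L_i(Δω),
    L_i(Δω) = A_i / (1 + 4((Δω − Δω_i)/σ_i)²),

where `A_i` is the peak fractional saturation, `σ_i` the full width at half
maximum in ppm and `Δω_i` the pool's chemical shift. `Z_base` is 1 with
perfect saturation efficiency and is fixed at 1.0 by default (optionally
fitted in [0.9, 1.0]). Some presentations of this line shape carry a
percent-scale baseline constant ("100 −") inside each `L_i`; that constant
is deliberately **not** part of the line shape here — the model subtracts
pool components from a single explicit baseline, and duplicating the
baseline inside each component would double-count it. All amplitudes are
fractions; percent-scale bounds are divided by 100.

### MT removal sign convention

The MT pool enters the *measured* spectrum as a reduction of Z. Removing
its contribution therefore restores the fitted component:

    Z_corr(Δω) = Z(Δω) + L_MT(Δω).

On a DS+MT-only spectrum with a perfect fit this leaves exactly
`Z_corr = Z_base − L_DS`, i.e. a spectrum with the MT dip removed; the
corrected values exceed the measured Z wherever the MT component is
nonzero. An alternative, inverse-spectrum formulation performs the removal
after inversion, using the MT pool's own z-spectrum `Z_MT = Z_base − L_MT`:

    1/Z_corr(Δω) = 1/Z(Δω) − 1/Z_MT(Δω).

The two routes are not algebraically identical. The Z-space form is the
default (`variant="z_space_subtraction"`); the inverse-space form is kept
as a flagged variant and recorded in provenance. Under the inverse-space
reading, `1/Z_MT` is finite as the MT amplitude goes to zero, which is the
only dimensionally sane interpretation of that formulation.

## Two-pool fit

Per voxel, bounded trust-region least squares (`scipy.optimize.
least_squares`, analytic Jacobian, xtol = ftol = gtol = 1e-10, ≤500
evaluations) estimates DS and MT amplitude and width from one deterministic
starting point; centres are fixed at 0 ppm (DS) and −2.4 ppm (MT), never
fitted. Bounds and initial values (fraction / ppm):

| parameter    | lower | upper | initial |
|--------------|-------|-------|---------|
| DS amplitude | 0.20  | 1.00  | 0.60    |
| MT amplitude | 0.00  | 0.90  | 0.35    |
| DS width     | 0.1   | 5     | 2.55    |
| MT width     | 10    | 100   | 55      |

Any parameter ending within 1e-6 of a bound sets the `at_bound` flag; a DS
amplitude pinned at the 0.20 lower bound marks a likely non-tissue voxel.

**Label-window exclusion.** By default the fit omits offsets in
[1.2, 4.8] ppm — the +3.0 ppm label resonance ± 1.2× its nominal FWHM —
from the fitted points (they are still corrected afterwards). The DS+MT
background model cannot describe the amine dip; fitting through it pulls
the background parameters and leaks label signal into the reference side
of the corrected spectrum. With the window excluded, a small amine pool
leaves the corrected value at −3.0 ppm unchanged to ≲1e-3 and the
label-side contrast scales linearly with amine amplitude (doubling ratio
≈ 2.05 for amplitudes ≤ 0.05). Pass `exclude_ranges=()` to fit every
offset.

## Contrasts at the label offset

With `Δω = 3.0` ppm (glutamate amine protons):

* `GluCEST = 100·(Z(−Δω) − Z(+Δω))/Z(−Δω)` — legacy asymmetry, percent;
* `MTRasym_corr = Z_corr(−Δω) − Z_corr(+Δω)`;
* `MTR_Rex_corr = 1/Z_corr(+Δω) − 1/Z_corr(−Δω)`;
* `AREX_corr = MTR_Rex_corr × R1` in 1/s, an elementwise product that
  holds bitwise wherever both factors are defined.

Values at ±3.0 ppm are taken from the measured (B0-recentred) spectra via
the same cubic interpolator used everywhere, even though ±3.0 are grid
points, so recentred and non-recentred spectra follow one code path.
Voxels with non-positive `Z_corr` at either side are marked invalid rather
than clipped — a clipped 1/Z would bias ROI means — and invalidation
counts are reported.

## Field maps

**B0 (WASSR).** The direct-saturation dip of the low-power WASSR spectrum
is symmetric about the true water frequency. The shift estimate is the
centre δ minimizing the mean squared difference between the cubic-spline
interpolated spectrum and its mirror about δ (maximum-symmetry centre):
coarse grid at 0.01 ppm over ±0.5 ppm, fine grid at 0.001 ppm, final
parabolic refinement. Spectra with dip depth < 0.05 are flagged flat and
assigned shift 0. On noiseless shifted spectra the estimator is unbiased
to ≤0.005 ppm over ±0.3 ppm.

**Recentring** resamples each measured spectrum at `Δω + δ` onto the fixed
offset grid (cubic spline), so all voxels share one grid downstream; grid
points whose source position falls outside the measured range are set
invalid and counted.

**B1 (AFI).** With `r = S2/S1` and `n = TR2/TR1` (defaults 160/35 ms,
nominal flip 60°), the actual flip is `α = arccos((r·n − 1)/(n − r))`,
the exact algebraic inverse of the idealized AFI steady-state ratio.
Ratios outside `(1/n, 1]` are flagged invalid. The B1 map is computed and
reported for quality control but **not** applied to the CEST contrast — no
validated correction algorithm is part of this chain; a pass-through hook
exists.

## R1 mapping

Magnitude inversion-recovery data are fitted per voxel with

    S(TI) = m0 · |1 − f · exp(−TI·R1)|,   f = 1 + inv_efficiency ∈ [1, 2],

(f = 2 is perfect inversion; the inverted/equilibrium magnetization ratio
is −f, and the signed curve nulls at `TI = ln f / R1`). Polarity is
restored by a sign-flip search over candidate null indices around the
signal minimum; each candidate is fitted by bounded least squares and the
lowest residual wins. The canonical protocol uses 14 TIs from 6 to
8000 ms. Noiseless recovery is exact to ≲1e-6 relative; at 1% noise the
median relative error is ~0.6%.

Thin-slice maps are collapsed to the thick CEST slice by voxel-wise
averaging over valid slices; binary masks by a k-of-n vote — k = 2 of 5
for GM/WM/WM-lesion masks, k = 1 (any slice) for small cortical lesions —
after which lesion voxels are excluded from the normal-appearing masks.

## ROI statistics

Summaries report mean, median and a histogram (64 uniform bins over the
robust 1st–99th percentile range, configurable) over valid voxels only.
Group comparisons default to the classic pooled-variance two-sample t-test
(Welch by flag) and the paired t-test; a paired test with zero-variance
differences is an error. The partial Spearman correlation
rank-transforms x, y and the covariates (midranks at ties), residualizes
the x and y ranks on an intercept plus covariate ranks by least squares,
and reports the Pearson correlation of the residuals with a two-sided
p-value from the t approximation on `n − 2 − n_cov` degrees of freedom;
with no covariates this reduces exactly to ordinary Spearman rho. No
multiple-comparison correction is applied by default; the Bonferroni
threshold `α/m` is available for post-hoc reporting (0.05/38 → 0.0013).

## Synthetic phantom

The generator emulates the statistical structure the analysis assumes, on
a 2D single-slice grid (the acquisition this chain targets is a single
thick slice; IR series are generated as 5 thin slices to exercise the
collapsing rules). Default tissue classes (fraction / ppm / 1/s):

| class           | DS A/σ    | MT A/σ    | amine A/σ | R1   | S0   |
|-----------------|-----------|-----------|-----------|------|------|
| WM              | 0.60/2.6  | 0.30/60   | 0.018/1.5 | 0.83 | 0.80 |
| GM              | 0.55/2.3  | 0.15/55   | 0.036/1.5 | 0.50 | 0.90 |
| CSF             | 0.85/1.6  | —         | 0.004/1.5 | 0.23 | 1.00 |
| WM lesion       | 0.60/2.6  | 0.22/60   | 0.027/1.5 | 0.70 | 0.82 |
| cortical lesion | 0.55/2.3  | 0.13/55   | 0.038/1.5 | 0.45 | 0.90 |

MT is largest in WM, small in GM and absent in CSF; R1 values are
7T-realistic (WM > GM > CSF) and reduced in lesions. The amine amplitudes
follow the ~2:1 GM:WM glutamate concentration ratio, with WM-lesion amine
elevated ~1.5× over normal-appearing WM — the orderings this kind of study
reports. An optional rNOE pool (0.02/3.0 at −3.5 ppm) can be enabled to
probe robustness to background-model mismatch.

Nuisance defaults: smooth low-order-harmonic B0 field with max |δ| =
0.10 ppm (bound 0.3), smooth B1 field 1 ± 0.10, linear multiplicative
drift 1.00 → 0.97 across the dynamics, additive Gaussian noise with SD
0.005 of the unit S0 scale (Rician by flag; Gaussian is the high-SNR
default and keeps the stage oracles analytic). Geometry (elliptical head,
GM rim, WM interior, central CSF, two lesions) and both fields are
deterministic functions of the configuration; all noise streams take
explicit integer seeds and no global random state is touched.

**What the phantom does not emulate** — and hence what passing tests do
not show about real data: spectra are sums of Lorentzians (the same family
the analysis fits), not Bloch–McConnell solutions, so there is no
saturation-power dependence, exchange-rate physics, or lineshape mismatch
beyond the optional rNOE pool; B1 inhomogeneity perturbs only the AFI
forward model (optionally pool amplitudes) rather than the saturation
efficiency; geometry is cartoon-like; volumes are perfectly co-registered
(registration is out of scope; hooks accept precomputed transforms but
apply none by default); and the amine amplitude is a free parameter, not a
concentration–exchange-rate product.

## Problem sizes and numerical choices

The shipped validation runs use grids of 8×8 to 64×64 voxels, 200-draw
parameter-recovery sweeps, 100-draw noisy R1 sweeps, a 2000-replication
null calibration of the t-test, and a 15-subject synthetic cohort at
32×32 — sizes at which every check completes in seconds while leaving the
estimators' behaviour fully exercised. Spline operations use not-a-knot
cubic splines (drift model is an interpolating spline through the 13
references by default; a smoothing variant is configurable). The WASSR
search clips to ±0.5 ppm; two-pool and IR fits run with the tolerances
stated above; ties in the IR polarity search resolve to the lowest
residual. Degenerate inputs (flat spectra, flat IR series, empty ROIs,
non-positive S0) are flagged or raised explicitly rather than silently
clipped.

## Known limitations

* The Lorentzian forward model cannot probe saturation-parameter
  dependence or exchange kinetics; conclusions about those require
  Bloch–McConnell simulation or phantoms.
* The MT pool is a symmetric Lorentzian centred at −2.4 ppm; true
  semisolid lineshapes (super-Lorentzian) are broader-tailed, and ≥3-pool
  decompositions are out of scope.
* The B1 map is informational; no B1 correction of CEST contrast is
  applied.
* The legacy GluCEST asymmetry is provided for comparison only; it
  retains MT asymmetry and T1 weighting by construction.
* Partial-volume effects of a thick slice, motion, and registration error
  are not modelled.
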