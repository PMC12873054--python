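# Methods

This note records the models, conventions and design choices behind
`renalperf`, in the spirit of a methods section: what is computed, under
which assumptions, and where the genuinely open choices were made.

## Signal model and units

All kinetic modeling operates on absolute signal enhancement,
S(t) − S₀, where S₀ is the per-voxel mean of the first
`n_baseline_frames` (default 3) pre-bolus frames. Signal is assumed
linear in contrast-agent concentration over the dose range of a
first-pass renal study; no conversion to gadolinium concentration (and
no T1 calibration) is performed, so Ktrans-like parameters are exact up
to the common signal–concentration proportionality, which cancels in the
Patlak regression because the tissue curve and the AIF share it.

Time is internal in **minutes**; rate constants (Ktrans, kep, Fp, PS)
are min⁻¹ and volume fractions (vp, ve) dimensionless. Reported units
multiply by 100: mL/100 mL/min for rates, mL/100 mL for volumes. The
acquisition grid is uniform, by default 65 frames at 6.6 s.

## Kinetic models

With Cp(t) the AIF and ⊛ convolution:

- **Patlak** — Ct = Ktrans·∫₀ᵗCp dτ + vp·Cp. Valid when backflux from
  the interstitium is negligible over the imaging window.
- **Extended Tofts** — Ct = vp·Cp + Ktrans·(Cp ⊛ e^(−kep·t)).
- **2-compartment uptake** — Ct = Cp ⊛ R with
  R(t) = Fp[(1−E)e^(−t/Tp) + E], E = PS/(PS+Fp), Tp = vp/(Fp+PS).
- **2-compartment exchange** — Ct = Cp ⊛ R with the biexponential
  residue R(t) = Fp[A·e^(−αt) + B·e^(−βt)], where −α, −β solve
  s² + s·((Fp+PS)/vp + PS/ve) + Fp·PS/(vp·ve) = 0 and
  A = (σ−α)/(β−α), B = (σ−β)/(α−β) with σ = PS/vp + PS/ve. R(0) = Fp
  and ∫₀^∞R = vp + ve (mass conservation), both covered by tests. Equal
  roots fall back to the confluent (1 + (σ−α)t)e^(−αt) form rather than
  erroring; for strictly physical parameters the discriminant is
  positive, so this branch is purely defensive.

The residue-function conventions for the two-compartment models follow
the standard flow/PS parameterization of the DCE literature; the package
documents them here because different softwares differ in whether Fp is
folded into R.

**Quadrature.** Every integral and convolution uses the trapezoidal rule
on the acquisition grid. This single choice makes the nesting limits
exact discrete identities — extended Tofts with kep = 0 equals Patlak to
machine precision, exchange with PS = 0 equals uptake with PS = 0 — which
the test suite asserts at 1e−9 or better. Halving the frame interval
(with a linearly interpolated AIF) moves every forward curve by < 1% in
max norm for transit times resolved by the 6.6-s grid.

## Fitting

- **Patlak** is linear: OLS of Ct on [∫Cp, Cp] over the fit window.
  Negative estimates are clipped to zero (the parameters are physical
  non-negative quantities) and the voxel is flagged; the reported RSS is
  that of the unclipped solution so model comparison is not distorted.
- **Fit window**: from the detected bolus arrival (first frame where the
  AIF exceeds its baseline mean by 5 baseline SDs) to the last frame;
  overridable. The baseline length (3 frames ≈ 20 s) and the window are
  configurable because acquisition protocols differ.
- **Nonlinear models** use `scipy.optimize.least_squares` (trf, tight
  tolerances) with box bounds — rates in [0, 10] min⁻¹, volumes in
  [0, 1], generous for renal physiology — and 8 seeded Latin-hypercube
  start points (rates sampled log-uniformly from 1e−3). The exchange
  model is fitted in (Fp, PS, vp, fe) with ve = fe·(1−vp) so the simplex
  constraint vp + ve ≤ 1 becomes a box constraint. Identical seeds give
  bit-identical fits.
- **AIC** = n·ln(RSS/n) + 2(k+1), counting the estimated noise variance
  as a parameter; RSS = 0 maps to −∞ (a perfect fit dominates) and is
  flagged. AICc is available as an option but off by default so one
  canonical score governs selection; ties are broken toward fewer
  parameters.

A caveat worth stating: on noisy Patlak-generated curves, a richer
nested model beats the AIC penalty with probability ≈ ½·P(χ²₁ > 2) ≈ 8%
per boundary-constrained extra parameter, so with three richer
competitors the Patlak selection rate is theoretically capped around
82–85% even when Patlak is the true model. The package's measured rate
(~82/100 at the default study conditions) sits exactly there; Patlak
remains the clear plurality choice, consistent with selecting it as the
operating model at this temporal resolution.

## Pipeline

Per animal: (1) optional motion correction, (2) enhancement, (3) AIF =
per-frame median over the aorta ROI, zeroed before the detected bolus
arrival, (4) per-voxel Patlak maps inside each kidney ROI, (5) per-ROI
medians over unflagged voxels. Because all voxels share the AIF design
matrix, the voxel-wise OLS is a single multi-RHS solve — identical to
per-voxel fits and independent of voxel order.

Motion correction is **translation-only**: per-frame integer shifts
within ±3 voxels, chosen by exhaustive search maximizing normalized
cross-correlation against the voxel-wise temporal median volume; shifts
wrap circularly at the volume edge. Flat frames and frames whose best
correlation stays below 0.2 are left unshifted and flagged. This is a
deliberate simplification of full affine/non-rigid registration: it is
exactly invertible on the phantom (so correctness is testable) and
adequate for bulk motion; deformable registration is out of scope.

Whether ROI medians should come from per-voxel maps or from a fit of the
ROI-median curve is ambiguous in practice; the default is per-voxel maps
then median (`curve_first=False`), with the curve-first alternative one
flag away. On noiseless phantoms the two agree to numerical precision.

## Exact statistics

Unpaired comparisons use the exact Mann–Whitney U test: U counts pairs
with the second sample larger (+½ per tie); the two-sided p is
2·min(P(U≤u), P(U≥u)) capped at 1, under the exact null over all
C(n1+n2, n1) assignments, computed by integer subset-sum dynamic
programming (identical to enumeration, verified against it). Paired
comparisons use the exact Wilcoxon signed-rank test: zeros dropped,
average ranks for tied magnitudes, null over all 2ⁿ sign assignments.
This 2·min-tail convention reproduces every reproducible printed
p-value of the motivating study design (0.008, 0.125, 0.250, 0.313 —
and 2·P(U≤5) = 38/252 = 0.1508 → 0.151 at n = 5/5).

Effect sizes are rank-biserial correlations — (favorable −
unfavorable)/(n1·n2) unpaired, (W⁺−W⁻)/(n(n+1)/2) paired — signed so
that positive favors the first-named group (16h − 30min, transplant −
native). Shift estimates are Hodges–Lehmann: median of pairwise
differences (unpaired) or Walsh averages (paired), with exact CIs from
the k-th extreme order statistics, k = (critical value at α = 0.05) + 1.
When the requested coverage is unattainable at the sample sizes, the
widest attainable interval is returned and flagged. The paired
Hodges–Lehmann analog is included so paired comparisons report CIs in
the same layout as unpaired ones. α = 0.05; no multiplicity adjustment
(exploratory design). Printed values use half-up rounding, the
convention of published tables.

## Phantom generator

The phantom emulates the study's statistical structure, not renal
anatomy: a 24×24×6 volume with four rectangular regions (aorta ~48
voxels; transplant, left and right native kidneys ~196 voxels each — a
desk-scale stand-in for the ~1,500–2,000 voxels of a real ROI,
configurable upward). The AIF is a gamma-variate bolus (peak 26.4 s
after an arrival at frame 5) plus a biexponential washout, unit peak.
Kidney voxels follow the Patlak forward model with per-animal
parameters; baseline S₀ = 100 with SD-2 voxel jitter (static texture
that also anchors registration); Gaussian noise with σ = 5% of the AIF
peak is added on the enhancement scale (noise is Gaussian rather than
Rician because modeling operates on enhancement differences, not
magnitude signal). Optional episodic bulk motion displaces a minority of
frames (default 30%) by integer shifts, so the temporal median remains a
faithful registration reference; every injected shift is recorded.

Per-animal truths are log-normal with the group median exact and the
log-sigma fitted to the interquartile ratio, σ = ln(q3/q1)/(2·0.6745).
Fitting each tail separately to reproduce the printed quartile positions
exactly was considered and rejected: with the strongly asymmetric
short-ischemia Ktrans IQR it implies an upper tail so heavy that the
groups overlap in ~25% of replicates, which contradicts the separation
the group medians are meant to encode; the IQR-width fit preserves the
printed spread while keeping the group contrast. Default group levels
(reported units): transplant Ktrans 2.87 [2.45–3.03] (16 h) vs 0.91
[0.90–1.42] (30 min); transplant vp 21.89 [17.28–23.22] vs 29.02
[24.99–37.15]; native kidneys shared across groups at Ktrans 0.85
[0.62–1.05] and vp 31.5 [27.5–33.8], pooled midpoints of the per-side
native levels. n = 5 animals per group.

What the phantom does **not** model — and what passing tests therefore
do not show about real data: partial-volume and T1/T2* signal physics,
Rician magnitude noise, within-kidney heterogeneity (kidneys are
homogeneous by default; two-level subregions are exercised in tests),
non-rigid deformation, AIF dispersion/delay differences between animals,
and inter-scanner variability.

## Degenerate inputs and numerical conventions

- Zero AIF in the fit window → explicit singular-design error.
- All-zero tissue curve → Patlak fits exactly with RSS 0 (flagged
  "perfect fit"; AIC −∞; selection falls to fewest parameters).
- Fully tied paired samples → comparison reports p = 1, effect 0 (the
  bare signed-rank test refuses all-zero differences).
- ROI summaries use only unflagged voxels; at low Ktrans operating
  points the clip-at-zero flag excludes voxels whose OLS slope went
  negative under noise, which biases that ROI median slightly upward —
  visible in the 30-min group at default noise, and accepted as the
  documented cost of reporting physical (non-negative) maps.
- Incomplete acquisitions: the `fit` command excludes animals with fewer
  than `--min-frames` acquired frames (default 50 of 65) and logs every
  exclusion; nothing is dropped silently.
- Determinism: every stochastic component (phantom, multi-start, CLI)
  is driven by explicit seeds; identical seeds give byte-identical
  outputs.

## Problem sizes used in the validation suite

Parameter-recovery and model-selection checks use 200 and 100 noisy
curves on the 65-frame grid; the end-to-end check runs 100 phantom
studies of 10 animals each. These sizes keep the full suite in the
order of a minute while leaving the Monte-Carlo margins (e.g. 98/100
observed vs the 90/100 requirement) far from their thresholds.
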