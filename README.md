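# renalperf

Quantitative DCE-MRI perfusion analysis for small-animal renal (transplant)
studies, with the exact small-sample statistics such studies require.

Dynamic contrast-enhanced MRI captures the first pass of a gadolinium bolus
through the kidney. On the absolute signal enhancement S(t) − S₀, the Patlak
model describes each voxel's tissue curve as

    Ct(t) = Ktrans · ∫₀ᵗ Cp(τ) dτ + vp · Cp(t)

where Cp is the arterial input function (AIF, here taken from an abdominal
aorta ROI), **Ktrans** (mL/100 mL/min) is the volume transfer constant — a
surrogate of capillary permeability — and **vp** (mL/100 mL) is the fractional
plasma volume. The package provides:

- **Forward kinetic models** — Patlak, extended Tofts, two-compartment uptake
  (2CUM) and two-compartment exchange (2CXM) — on a uniform acquisition grid
  (default 65 frames at 6.6 s), sharing one trapezoidal quadrature so nested
  limits agree to machine precision.
- **Fitting and model selection** — linear (OLS) Patlak fits per voxel;
  bounded multi-start nonlinear least squares for the alternatives; model
  comparison by the Akaike information criterion.
- **A voxel-wise pipeline** — enhancement computation, optional translation
  rigid motion correction, AIF extraction, per-ROI Patlak parameter maps and
  median summaries for the transplanted, left and right native kidneys.
- **Exact nonparametric statistics** — exact Mann–Whitney U (unpaired) and
  Wilcoxon signed-rank (paired) tests, rank-biserial effect sizes, and
  Hodges–Lehmann shift estimates with exact distribution-free 95% CIs. Null
  distributions are computed by integer dynamic programming equivalent to
  full enumeration; no normal approximations.
- **A phantom generator** — synthetic 4D studies with aorta and kidney
  regions, per-animal ground-truth parameters drawn from configurable
  median/IQR-matched log-normal group distributions, Gaussian noise and
  optional bulk motion, so the entire pipeline is testable end to end.

## Worked example

Simulate a two-group study (5 animals per ischemia group), fit it, and
compare the groups:

```sh
renalperf simulate --out demo/study --seed 7
renalperf fit --manifest demo/study/manifest.json --out demo/fit --no-motion-correction
renalperf stats --summary demo/fit/summary.tsv --out demo/report
```

The simulator prints the ground-truth medians it drew (reported units):

```
group roi_label       true_ktrans  true_vp
16h   transplant         2.90        26.73
30min transplant         0.92        37.29
...
```

and `stats` prints the comparison report (abridged):

```
  comparison     parameter  p_two_sided  effect_size  hl_estimate  hl_ci_low  hl_ci_high
16h_vs_30min median_ktrans     0.007937     1.000000     1.168380    0.62199     1.59201
16h_vs_30min     median_vp     0.222222    -0.520000   -11.627100  -24.73360     3.21100
```

Reading: transplanted-kidney Ktrans is significantly higher after prolonged
(16 h) cold ischemia than after short (30 min) ischemia — exact two-sided
p = 0.008 with complete separation (rank-biserial effect 1.0) and a
Hodges–Lehmann shift of ≈1.2 mL/100 mL/min — while vp tends lower (negative
effect size) without reaching significance at these sample sizes. That is the
microvascular signature of ischemia-reperfusion injury: leakier capillaries,
reduced perfused plasma volume.

The same operations are available as a library (`renalperf.fit_patlak`,
`renalperf.select_model`, `renalperf.compare_groups`, ...); see the module
docstrings and `docs/methods.md` for the modeling details and conventions.

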