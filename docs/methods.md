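# Methods

## Quantification model

Every compound's detector response is assumed linear over its working
range: `area = slope · concentration + intercept`, fitted by unweighted
ordinary least squares (the package deliberately offers no 1/x weighting or
nonlinear calibration; reported curves for this assay family are plain
linear regressions with R² > 0.999).

Two quantification routes share this model:

- **ESM** (external standard method): each compound is inverted through its
  own curve, `C = (A − b)/m`. Negative inversions (area below the
  intercept) clip to zero with a warning.
- **QAMS** (single-marker): only the reference compound (DISS) is inverted
  through a curve; targets follow from `C_i = f_si · C_s · A_i / A_s`.

The relative calibration factor `f_si = (A_s/C_s)/(A_i/C_i)` is computed on
calibration levels paired by position — in this assay the levels are an
injection-volume series (0.1–1.4 µL of the mixed working standard, eight
levels by default), with the effective on-column concentration scaling
linearly with volume relative to the nominal 1.0 µL injection. The final
factor is the **unweighted mean** of the per-level factors.

Two algebraic facts drive the test design:

1. a common multiplicative detector gain cancels exactly in `f_si`, so the
   factors are robust to instrument/column/temperature/flow-rate changes
   that act as a shared gain;
2. for a zero-intercept detector, substituting `A = m·C` into the two
   equations collapses QAMS onto the ESM inversion — the two routes are
   analytically identical, and the suite asserts agreement to 1e−12
   relative on noiseless data. With nonzero intercepts QAMS acquires a
   small bias at concentrations where `b` is non-negligible against `m·C`;
   the published curves have `|b|/(m·C)` well below 1% across their linear
   ranges, which is why the ESM-vs-QAMS cosines stay above 0.999.

"Exact" invariances (gain cancellation, zero robustness RSD without noise)
hold in real arithmetic; tests assert them to 1e−10–1e−12 to allow for
floating-point rounding of the area ratios.

## Detection limits

- LOD = 3·σ_noise/slope and LOQ = 10·σ_noise/slope (signal-to-noise 3:1 and
  10:1), with σ_noise the baseline noise SD in counts.
- MDL = SD · t(n−1, one-sided 0.99) and MQL = 10 · SD from n low-level
  replicate spikes. The Student-t quantile is taken from the exact
  distribution (3.143 for n = 7; the assay literature rounds to 3.14).
  Printed MQL/MDL pairs from the source table are not all consistent with
  the 10/t ratio after rounding, so the ratio law is asserted on synthetic
  data only.

## Uncertainty budget

`U = k·c·√(ur_sample² + ur_cal² + ur_true² + ur_rep² + ur_lod²)` with
`ur_cal = SD_RRF/√n_cal`, `ur_rep = SD_results/√n_rep`, `ur_lod = LOD/c_det`
and default coverage factor k = 2. The two SD inputs are accepted as
*relative* SDs (fractions): the source formulas label the components
"relative" without dividing by a mean, and only the relative reading makes
every term under the root dimensionless. No published numeric budget exists
to cross-check, so tests assert the structural laws (homogeneity in k and
c, single-component collapse, 3-4-5 quadrature).

## Chemometrics

- **Hierarchical clustering**: between-groups (average) linkage on squared
  Euclidean distances of the raw mg/g values — the defaults of the
  statistics package used for the original analysis, which names neither
  linkage nor metric; Ward and complete linkage are exposed as options.
  Merge heights map linearly onto a 0–25 "rescaled distance" axis (final
  merge at 25), so a published cut at rescaled distance 9 can be applied
  directly. Under these defaults the embedded panel cut at 9 reproduces the
  published four-group membership exactly. Clusters are labelled G1, G2, …
  by first-sample appearance.
- **Radar coordinates**: compound j of p at angle 2πj/p, radius = content
  (optionally per-compound max-normalized); polygons close by repeating the
  first vertex, and a shoelace area summarizes overall quality.
- **Discriminant analysis**: canonical functions from the eigenvalues of
  `W⁻¹B` (within/between scatter); variance shares are
  100·λ_k/Σλ. Fisher classification functions use the pooled within-group
  covariance `S = W/(n−g)`: `coef_g = S⁻¹m_g`,
  `const_g = −½·m_gᵀS⁻¹m_g + ln(prior_g)`, with equal priors by default
  (again the source package's default; proportional priors are available).
  A ridge of 1e−8·trace(S) is added only when S is numerically singular
  (condition number > 1e12), with a warning. Leave-one-out cross-validation
  refits the model per fold; folds that would leave a group with fewer than
  two training samples are skipped with a warning and excluded from the
  percentage.

### Variable order of the published classification functions

The embedded Fisher model orders X1–X9 by chromatogram elution:
sibiricose A5, sibiricose A6, sibiricaxanthone B, glomeratose A,
polygalaxanthone III, tenuifoliside B, DISS, tenuifoliside A,
tenuifoliside C. One passage of the source text instead swaps X4/X5
(polygalaxanthone III before glomeratose A); under that mapping the printed
functions misassign three samples (87.0%), while the elution order
reproduces the reported 100% original classification, so the elution order
is taken as authoritative. Conversion from the concentration-table column
order (reference first) is explicit via `ConcentrationMatrix.reorder`.

## Synthetic data

The generator emulates the study design, not raw chromatograms: integrated
areas only (no retention drift, co-elution or peak shapes).

- Detector: per-compound slopes/intercepts default to the published curve
  metadata; conditions act as a single multiplicative gain shared by all
  compounds, making RCF robustness true by construction.
- Noise: proportional area noise `noise_cv` (default 0.004, i.e. 0.4%, the
  midpoint of typical intra-day repeatability of 0.19–0.83% for
  well-resolved UPLC peaks) plus optional additive counts noise `noise_sd`
  (default 0). The default is a calibration of the simulator to realistic
  repeatability, not a claim about any particular instrument.
- Batches: four group profiles default to the group mean vectors of the
  embedded panel; true contents are `mean · (1 + N(0, cv))` truncated at
  zero with `cv = 0.10` — a round figure of the same order as the
  within-group scatter observed in the panel (per-compound CVs 0.07–0.21).
  Truncation is preferred over log-normal sampling to keep group means
  interpretable; at cv < 1 truncation is rare. Contents convert to solution
  concentrations via the extraction parameters (default 1.0 g powder into
  25 mL, so 40 mg/L per mg/g).
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give identical peak tables, and the pipeline derives per-stage
  substreams from a single config seed.

Passing tests on these data show the pipeline's algebra and statistics are
correct under the stated noise model; they do not validate peak
integration, matrix effects, or non-multiplicative condition effects on
real instruments.

## Problem sizes

Tests and the reproduction scripts run entirely on the 23 × 9 embedded
panel and on simulations of comparable scale (4 groups × 4–6 batches,
eight-level calibration series, 50–200 seeded replicates for the
stochastic checks), which keeps the full suite under a few seconds.

## Known limitations

- Single-reference QAMS only; multi-marker variants are out of scope.
- Compound identities are taken as given (no retention-time matching).
- The per-sample minimum nine-component total of the embedded panel
  recomputes to 12.04 mg/g from the printed two-decimal values versus the
  published 12.053 mg/g (0.11% apart, beyond the 0.1% check applied to the
  totals); the published figure evidently derives from unrounded source
  data, and the corresponding check is reported as failing rather than
  loosened.
- Concentrations below the reference LOD propagate as computed values with
  a warning-level QC path rather than being zeroed, preserving matrix
  completeness for the chemometrics.
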