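# Methods

## Synthetic cohort generator

The generator produces one-dimensional ¹H spectra on a shared ppm grid for
an unbalanced two-group design (defaults: 6 controls, 7 cases — the study
design this package models). Each sample is

    intensity(δ) = Σ_m c_m · f_m Σ_peaks h · γ² / ((δ − δ₀ − η_m)² + γ²)
                   + baseline(δ) + ε(δ)

where `c_m` is the metabolite's base concentration (an arbitrary amplitude
of order 1 from the template library), `f_m` its group fold change (1 for
controls and for unperturbed metabolites), `h` and `γ` the relative height
and Lorentzian half-width at half-maximum of each line, `η_m` a per-sample,
per-metabolite chemical-shift jitter, and ε i.i.d. Gaussian noise.

The template library (`src/stressnmr/data/metabolite_templates.yaml`, one
editable file) holds 16 named metabolites with standard reference shifts
(lactate δ1.33/4.11, the glucose anomerics δ5.23/δ4.64, creatine
δ3.03/3.93, taurine δ3.26/3.42, aromatic NAD⁺ singlets δ8.1–9.3, allantoin
δ5.39, nicotinate and nicotinamide *N*-oxide aromatics, succinate δ2.41,
acetone δ2.23, valine δ0.99/1.04, threonine δ1.32/4.25, formate δ8.46,
alanine δ1.48, creatinine δ3.05/4.06). Multiplet fine structure is
collapsed to a few lines per metabolite, which is indistinguishable from a
true multiplet at 0.005-ppm binning resolution.

### What the nuisance terms emulate — and what they do not

The generator emulates spectra *after* instrument processing (phasing,
apodization, baseline correction, referencing); FID-domain physics,
J-coupling and pH-dependent shifts are out of scope. The nuisance defaults
are therefore post-correction residuals:

- `noise_sd = 0.005` intensity units per point, against peak heights of
  0.3–1.2: peak signal-to-noise of roughly 60–240, typical of a good
  500-MHz acquisition.
- `shift_jitter_sd = 0.0005` ppm (≈0.25 Hz at 500 MHz): the residual
  per-metabolite position scatter left after referencing, well below the
  0.005-ppm bin width by design. Jitter is drawn once per sample per
  metabolite and moves all of that metabolite's lines together.
- `baseline_amplitude = 0.002`: a slow sinusoid whose phase *and* period
  (0.5–1.5 cycles over the axis) are random per sample. Two points matter
  here. First, the amplitude sits at or below the noise floor — the usual
  acceptance criterion for a corrected baseline; a residual baseline far
  above the noise floor would contradict the premise that correction
  already happened. Second, the per-sample period randomization makes the
  residual *shapes* differ between samples. A fixed-period sinusoid with
  only a random phase spans exactly a two-dimensional subspace across
  samples (sin and cos of one frequency); that coherent low-rank structure
  loads on every bin simultaneously and cannot be removed by a single
  orthogonal OPLS component, which is not how corrected real baselines
  behave.

Because passing tests are claims about this generator, they show that the
chain behaves correctly for well-corrected spectra with known effects;
they do not certify performance on badly phased or drifting raw data, on
strongly pH-shifted peaks (citrate-like behaviour), or on matrices with
hundreds of overlapping resonances.

Concentrations are deterministic per group — between-sample biological
variance is not modeled beyond the nuisance terms, so the fold change and
the noise/jitter levels fully determine detectability. Determinism: the
design's single seed drives one `numpy` generator; identical designs give
bit-identical cohorts.

## Preprocessing

**Reference calibration** is a rigid axis shift placing the tallest point
of a search window at the reference position (TSP δ0.00; lactate CH₃ δ1.33
for plasma). True lineshape deconvolution needs the FID, which is never
modeled; rigid alignment is sufficient for binned integrals. The pipeline
skips calibration by default because the generator produces referenced
axes; the operation is available for externally supplied spectra.

**Binning** uses half-open `[low, low + 0.005)` buckets anchored at the
axis minimum. Bin values are trapezoid integrals computed from the
cumulative integral interpolated at bin edges, so the bin total equals the
whole-axis quadrature to round-off (the conservation invariant is tested
at 1e−9 relative). Integrals, not mean intensities, are the bin statistic;
the normalization target (total area = 100) is configurable.

**Exclusion** drops bins whose *centers* fall in a window — deterministic
and order-independent, at the cost of edge bins whose area partially
overlaps a window. Windows: plasma δ5.40–5.90 and 4.20–5.10 (urea,
residual water), urine δ5.35–5.90 and 4.14–5.25, tissue δ4.67–5.22 and
3.31–3.40 (water, methanol).

**Normalization**: total-area scaling to 100 is the default (the
historical choice for binned biofluid spectra). Note its known coupling:
a large unbalanced aggregate effect (many metabolites moving the same way)
shifts all other bins oppositely. Probabilistic quotient normalization —
divide each row by the median ratio to the cohort median spectrum — is
available and preferable when single metabolites change strongly.

## Chemometrics

PCA is computed by SVD of the mean-centered matrix; explained-variance
fractions are σ²ᵢ/Σσ². OPLS-DA encodes class as ±1 (centered), normalises
w ∝ Xᵀy, and per orthogonal component removes from X the loading direction
orthogonal to w before computing the predictive score from the deflated
matrix. Defaults: one orthogonal component (the minimal OPLS-DA, matching
a two-dimensional score plot) and Pareto scaling (divide centered columns
by √SD, sample convention n−1; zero-variance columns pass through with
divisor 1 and a warning). The predictive score is oriented so the case
group's mean is positive, making "positive loading = elevated under
stress" stable across runs.

Correlation and covariance loadings are computed between the predictive
score and the *scaled but undeflated* matrix, so they remain interpretable
as metabolite-vs-class association measures; both r and covariance are
exported since loading-plot colourings differ between conventions.

Q² = 1 − PRESS/SS(y centered) uses 7-fold venetian-blind (interleaved by
index) cross-validation; scaling and the model are refit on each training
split, preventing leakage. Prediction removes orthogonal variation from
the held-out rows before scoring. A fold whose training split loses a
class raises a degenerate-fold error naming the fold.

Null behaviour worth knowing: with 13 samples, the cross-validated Q² of a
label permutation is negative on average (≈ −0.4) but has a standard
deviation of ≈ 0.4, so roughly 15–20 % of permutations land above zero by
chance. This is a small-sample property of the statistic, not an
implementation artifact — an independent PLS implementation (R/mixOmics,
one component, 7-fold CV) reproduces it on identical matrices and
permutations. Permutation summaries over a few hundred permutations are
the reliable readout; a single permutation's sign is not.

## Discrimination

The critical value r* = t₁₋α/2,df/√(t² + df) gives 0.7545 at α = 0.05,
df = 5; the fixed cutoff 0.755 (as conventionally printed) is the default,
with `computed` mode deriving r* for any (α, df). The df = 5 convention is
taken as given rather than re-derived from the 6-vs-7 design; note it is
conservative for 13 samples (the 13-sample critical value would be 0.553).

Bins map to metabolites through ppm windows around each template line
(default half-width 0.015 ppm); a bin inside several windows goes to the
nearest line center. A metabolite is reported when any of its bins passes
the cutoff, with the signed r of largest magnitude as its summary — the
package's documented choice for collapsing multiple resonances to one
table entry. Significant bins outside every window are retained under
`unassigned δ x.xxx` labels (with a warning) in a separate frame of the
table; they are written to the output but excluded from recovery metrics,
which score named metabolites against the simulated ground truth (TPR over
perturbed metabolites, false positives among unperturbed named ones).

With ~1700 retained bins at n = 13, the pure-chance rate of |r| > 0.755 is
about 0.3 % per bin, i.e. a handful of spurious bins per cohort — almost
all in unannotated noise regions. The per-metabolite null flag rate
measures ≈ 0.03, comfortably inside a 0.10 budget (nominal 0.05 plus
multiplicity slack); no correction beyond the fixed cutoff is applied by
default, matching practice, though Benjamini–Hochberg can be layered on
externally. A known failure mode, faithfully reproduced: in crowded
regions the shoulder of a strongly perturbed peak can cross the cutoff in
a neighbouring metabolite's window (lactate δ1.33 → threonine δ1.32),
which manual peak assignment in real studies exists to resolve.

## Biochemistry

Enzyme activity converts a net 290-nm absorbance change to U/mL via
Beer–Lambert: activity = ΔA_net·V_total·10⁶/(ε·d·V_sample·T) with the
assay constants V_total = 2.6×10⁻⁴ L, ε = 1.22×10⁴ L·mol⁻¹·cm⁻¹,
d = 0.6 cm, V_sample = 0.01 mL, T = 30 min; one unit forms 1 µM uric acid
per minute. Negative activities are returned with a warning, never
clipped — they are assay-QC information. XDH = XOR − XO operates on group
means, as activity tables report them.

The summary-statistic t-test is the pooled-variance Student test
(df = n₁ + n₂ − 2), the default of the statistics packages wet-lab tables
are typically computed with; it reproduces the published uric-acid
p = 0.082 exactly, which also settles an internal inconsistency in the
source tables (the footnote's "mean ± S.D." governs over a "± SEM" in the
text — with SEM the numbers are irreconcilable with the printed p). Welch's
variant is available. 2^−ΔΔCt is the standard closed form; swapping case
and control roles returns the reciprocal.

## Pipeline

One `RunConfig` drives simulate → preprocess → model → discriminate with a
single seed fanned out to stages by SHA-256 hashing (`stage_seed`), so any
stage can be rerun in isolation with identical randomness. Every stage
output is a re-loadable text artifact (tidy CSV, CSV+JSON sidecar, TSV,
JSON), and a provenance record stores the verbatim config, its hash and
package versions. Identical configs produce byte-identical tables.

## Problem sizes

Defaults were chosen once as a balance of realism and convenience: 10 001
axis points (0.001-ppm spacing, five points per bin), 13 samples, ~1700
retained plasma bins. Monte-Carlo summaries use 50 cohorts for recovery
and 100 for null flag rates and label permutations; at these sizes the
measured quantities (TPR ≈ 1.0 at 1.5-fold effects, null flag rate ≈ 0.03)
are far from their acceptance bounds, so sampling error in the summaries
does not affect conclusions.
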