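# stressnmr

¹H-NMR metabolomics of acute restraint stress, end to end: spectral
binning/exclusion/normalization, from-scratch PCA and OPLS-DA with
correlation-coefficient loadings, a Pearson critical-value cutoff for
discriminating metabolites, and the accompanying serum biochemistry
(xanthine-oxidoreductase enzyme activities, summary-statistic t-tests,
2^−ΔΔCt gene expression) — exercised on a synthetic two-group cohort
generator so every stage is testable without any external data.

## The scientific problem

Acute restraint stress in male rats produces a depression-like phenotype
accompanied by broad metabolic rewiring: hepatic NAD⁺/NADP⁺ depletion,
increased urinary excretion of NAD precursors (nicotinate, nicotinamide
*N*-oxide), and reduced serum uric acid with its downstream products
allantoin and allantoic acid. The proposed mechanism runs through xanthine
dehydrogenase (XDH), the NAD-dependent form of xanthine oxidoreductase
(XOR): less NAD, less XDH activity, less uric acid. Untargeted ¹H-NMR
profiling of plasma, urine and five tissue extracts from an unbalanced
design (6 non-stressed controls vs 7 stressed animals) supplies the
metabolomic evidence; serum biochemistry and enzyme assays supply the
functional readout.

This package implements the complete inference chain of such a study:

1. **Preprocessing** — spectra are integrated over 0.005-ppm buckets
   (half-open bins anchored at the axis minimum, trapezoid integrals that
   conserve the total integral exactly); urea/water windows are removed by
   bin center (plasma δ 5.40–5.90 and 4.20–5.10; urine δ 5.35–5.90 and
   4.14–5.25; tissue δ 4.67–5.22 and 3.31–3.40); each sample row is
   rescaled to a common total area (probabilistic quotient normalization
   available).
2. **Chemometrics** — mean-centered PCA for quality verification, and
   Pareto-scaled OPLS-DA for discrimination. With class membership
   y ∈ {−1, +1} (centered), the predictive weight is w ∝ Xᵀy; each
   orthogonal component is the part of the current loading orthogonal to w,
   deflated from X; the predictive score t = Xw is computed after
   deflation. Model quality is R²X (fraction of scaled-X variance modeled)
   and Q² = 1 − PRESS/SS(y) from 7-fold venetian-blind cross-validation
   with scaling refit per fold.
3. **Discrimination** — the correlation loading of bin j is the Pearson
   r between t and that bin across samples; a metabolite is declared
   discriminating when any of its annotated bins satisfies |r| > 0.755,
   the two-tailed p < 0.05 critical value at 5 degrees of freedom
   (t₀.₉₇₅,₅/√(t² + 5) = 0.7545). Positive r means elevated in the
   stressed group.
4. **Biochemistry** — enzyme activity (U/mL) from 290-nm absorbance pairs,
   activity = (ΔA_test − ΔA_blank)·V_total·10⁶/(ε·d·V_sample·T) with
   V_total = 2.6×10⁻⁴ L, ε = 1.22×10⁴ L·mol⁻¹·cm⁻¹, d = 0.6 cm,
   V_sample = 0.01 mL, T = 30 min; XDH = XOR − XO; pooled-variance
   two-tailed Student's t-tests directly from published mean/SD/n rows;
   and fold changes by 2^−ΔΔCt.

The published summary tables (serum biochemistry panel, the 30-metabolite
correlation overview, XOR/XO activity means) ship as small CSV files under
`src/stressnmr/data/` and are the inputs to the biochemical and filtering
computations.

## Worked example

The `analysis/` scripts run the chain on a synthetic plasma cohort with a
stress-like truth (lactate ×1.6 up, α/β-glucose ×0.6 down in the stressed
group):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_chemometrics.py
python analysis/04_discriminating_metabolites.py
python analysis/05_biochemistry.py
```

which prints (abridged):

```
simulated 13 spectra (6 control / 7 case), 10001 points over 0.0-10.0 ppm
binned 13 spectra at 0.005 ppm: 2000 bins, 280 excluded ..., 1720 retained
OPLS-DA: R2X = 0.309, Q2 = 0.826 (1 predictive + 1 orthogonal component, Pareto scaling)
synthetic cohort at |r| > 0.755: 4 discriminating metabolites
   metabolite             comparison         r  bin_ppm
alpha-glucose plasma_case_vs_control -0.949307   5.2325
 beta-glucose plasma_case_vs_control -0.844117   3.8925
      lactate plasma_case_vs_control  0.835520   4.1075
    threonine plasma_case_vs_control  0.948498   1.3075
recovery vs ground truth: TPR = 1.00, false positives = 1
published correlation table: 36 entries, 30 unique discriminating metabolites at 0.755
serum panel: 23 analytes tested (pooled t, df = 11); significant at p < 0.05: Ibil, Glc
uric acid: t = 1.916, p = 0.0818 (below-threshold trend)
XDH activity (non-stressed) = XOR - XO = 0.246 U/mL
XDH activity (stressed) = XOR - XO = 0.171 U/mL
```

All three perturbed metabolites are recovered with the expected signs; the
one false positive (threonine) is the classic crowded-region artifact — its
CH₃ doublet at δ 1.32 overlaps the elevated lactate CH₃ at δ 1.33, so a
shoulder bin is attributed to the nearest annotated neighbour. The serum
t-tests flag exactly indirect bilirubin and glucose, and uric acid lands on
the published below-threshold trend (p = 0.082). The same pipeline is
scriptable as a CLI: `stressnmr run-all --seed 4 --outdir results/run`,
with `simulate`, `preprocess`, `oplsda`, `discriminate` and `biochem`
subcommands for the individual stages.

## Layout

- `src/stressnmr/` — the library: `simulate` (cohort generator),
  `preprocess` (calibration/binning/exclusion/normalization),
  `chemometrics` (PCA, OPLS-DA, Q²), `discrimination` (critical r,
  metabolite selection, recovery), `biochem` (enzyme/t-test/ΔΔCt),
  `datasets` (published tables), `pipeline` + `cli` (orchestration).
- `analysis/` — numbered narrative drivers writing under `results/`.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
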