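# Methods

## Models

The package evaluates and fits two variants of the operational model of
cooperative agonism and allosterism, plus the four-parameter logistic
(4PL). All concentrations are molar; affinity and efficacy parameters are
carried in log₁₀ space (log K_A, log K_B, log τ_A, log τ_B, log αβ), which
is both how pharmacology tables report them (pK_B, Log αβ) and the scale on
which the least-squares problem is best conditioned.

The complete model's response surface, with the response bracket
N = τ_A (A+C)^nB (K_B + αβB) + τ_B·B·K_A^nB and occupancy bracket
D = (A+C)^nB K_B + K_A^nB K_B + K_A^nB B + α (A+C)^nB B, is
E = Em·N^nT/(D^nT + N^nT). The implementation applies (A+C) and K_A^nB
uniformly in every term of both brackets — the internally consistent form
of the operational-allosteric literature. In the comparative variant the
agonist is parameterised by its observed EC50, the exponent grouping is
(EC50^nB)^nT, and τ_A defaults to 1.

Two structural facts are easy to trip over and are asserted by the test
suite:

* With nT = 1 every fixed-B curve is an *exact* Hill curve of slope nB in
  (A+C) (the model is a degree-1 rational function of (A+C)^nB). Apparent
  Hill slopes can therefore only vary with modulator concentration when
  nT ≠ 1.
* A NAM with α = 0 depresses the response only where the competitive-like
  K_A^nB·B occupancy term dominates. At deeply saturating agonist the
  αβ·B numerator term *raises* the effective efficacy
  τ' = τ_A(1 + αβB/K_B) and the plateau climbs toward Em; the EC50-shift
  ceiling is (1+τ_A)/(τ_A·αβ), ≈ 1/αβ for efficacious agonists. Monotone
  inhibition in B is guaranteed only below roughly ten times the control
  EC50.

## Constraints and fitting

Global fits share one parameter vector across all modulator
concentrations and apply the standard constraint set: nT = 1, α = 0,
log τ_B = −1000 (τ_B underflows to exactly 0: no allosteric agonism), and
log K_B bounded in (−8, 0), i.e. K_B between 10 nmol/L and 1 mol/L — the
only scale on which those two bounds are mutually consistent. Everything
else (Em, log τ_A, log K_A or logEC50, nB, log K_B, log αβ) is free and
shared. The loss is unweighted ordinary least squares on normalized
responses; no robust reweighting is applied even where the model fits the
highest modulator concentrations imperfectly, because none is part of the
reference analysis.

Optimization runs on lmfit's trust-region least squares. Starts: log K_B
at −6.5, log αβ at −1, Em at the maximum observed response, log K_A (or
logEC50) at the vehicle curve's half-maximum crossing, nB at 2; ten
multistart restarts jitter the free log-scale parameters by ±0.5 log units
with a seeded generator, and the lowest-RSS solution wins, making results
bit-reproducible for a fixed seed. Standard errors are asymptotic, from
the Jacobian at the optimum. Parameters that end within 10⁻⁶ of a bound
are flagged censored; a dataset with no modulator present has log K_B and
log αβ fixed and flagged non-identifiable (K_B cancels from the
vehicle-only likelihood). Fits with fewer distinct design points than free
parameters + 1 raise an under-determined error rather than returning
garbage.

Per-curve 4PL fits are fully independent per (modulator concentration,
experiment); summary tables report mean ± SEM across experiments with
n = number of experiments, which reproduces the "± SEM (n)" convention of
per-concentration tables (not a pooled fit). Flat curves return a flagged
degenerate fit with infinite standard errors instead of raising.

Both pooled global fits (default) and the per-experiment route are
available, since reference analyses are ambiguous on this point.

## Synthetic data

The generators define the study conditions under which every stage is
validated:

* **Concentration-response plates.** Modulator at
  {0, 0.1, 0.3, 1, 3, 10} μmol/L; ambient agonist C = 0.1 mmol/L; 4
  independent experiments; agonist on 10 half-log points from 0.1 to
  30 mmol/L — the reference analysis never lists its agonist grid, so the
  default brackets a control LogEC50 of −2.94 with both plateaus sampled.
  Noise is additive Gaussian with SD = 5 % of Em, truncated at zero —
  deliberately simpler than real heteroscedastic plate noise, and
  sufficient for recovery testing. The default ground truth (Em = 193.56,
  τ_A = 5, nB = 2.91, log K_A ≈ −2.67) is chosen so the vehicle curve is
  exactly the control row LogEC50 = −2.94, E_max = 161.3 % ionomycin,
  Hill = 2.91.
* **Hill-trend surface.** Because nT = 1 surfaces cannot show a
  modulator-dependent Hill slope (see above), the declining-Hill signature
  is generated by a sub-linear transducer variant (nT = 0.5, nB = 4.4,
  pK_B = 8, log αβ = −1, τ_A = 5) on a wider 12-point agonist grid
  (0.03–100 mmol/L): rising effective efficacy under a saturating
  transducer flattens the apparent curve monotonically in B, mirroring the
  behaviour of cooperative receptors under NAM block. nT > 1 produces the
  opposite trend.
* **Washout plates.** Three arms (vehicle / modulator / modulator +
  washout); the washed arm sees an effective concentration
  residual_fraction × preincubation concentration, so residual 0 is a
  fully reversible ligand and 1 an irreversible one.
* **PTH time courses.** Sampling at {5, 10, 15, 20, 25, 30, 40, 70, 160,
  240, 370} min after the start of a 10-min infusion. Profiles are
  baseline + amplitude × s(t) with the phenomenological surge
  s(t) = (t/t_p)^a · e^(−λ(t−t_p)), λ = ln2/half-life, a = λ·t_p, whose
  mode is exactly t_p with an asymptotically exponential tail. This is a
  descriptive shape, not a mechanistic PK/PD model — no drug-PTH coupling
  is modelled. Presets: fast-reversible (peak 5 min, half-life 4 min,
  back within 10 % of baseline by 30 min) and slow-sustained (peak
  15 min, half-life 70 min, basal by ~6 h). Noise is multiplicative
  log-normal with unit mean and a configurable CV. Defaults: baseline
  30 pg/mL, amplitude 300 pg/mL, 3 animals per arm.

What passing these tests shows — and does not. Recovery under the
generators demonstrates the estimation machinery is correct and calibrated
under the stated noise model; it does not certify performance on real
plates, whose noise is heteroscedastic, whose curves deviate from the
model at high modulator concentrations, and whose raw data are not
available for comparison.

## Statistics

* **Dunnett many-to-one comparisons.** Adjusted p-values come from the
  equicorrelated multivariate-t distribution of the max-|t| statistic,
  evaluated by direct numerical integration (Gauss–Hermite over the shared
  control deviate, adaptive quadrature over the pooled-scale chi
  distribution) — no lookup tables. Unbalanced designs are handled through
  λ_i = 1/√(1 + n₀/n_i). The k = 1 case reduces to the pooled two-sample
  t-test to 10⁻⁶ in p; the suite cross-checks against an independent
  reference implementation and verifies familywise error 0.05 ± 0.01 on
  10,000 simulated nulls.
* **Repeated-measures two-way ANOVA** on PTH profiles: mixed-design ANOVA
  (between = compound, within = time) for the main effects, with
  per-timepoint unpaired t-tests corrected by Bonferroni (default; Šídák
  optional) across the time grid — the correction inside such analyses is
  rarely stated, so the conservative default is used. Arms must have
  disjoint animals and identical grids.
* **AUC** is the linear trapezoid of the PTH-time linear interpolant over
  the sampled range (first sample to 370 min by default), with no baseline
  subtraction unless requested — whether reference AUCs were
  baseline-corrected is unstated, so net area from the sampled origin is
  the default and a corrected mode is provided.
* **Washout verdict**: the washed arm is compared to the vehicle and
  modulator arms by unpaired t-tests on per-experiment LogEC50 and E_max;
  indistinguishable-from-vehicle ⇒ washed-out, indistinguishable-from-
  modulator ⇒ retained, otherwise partial. Zero-variance (noise-free)
  comparisons fall back to absolute tolerances (10⁻⁴ log units, 0.01 %
  response). With few experiments per arm the α = 0.05 equivalence
  reading misclassifies a small fraction of noisy full-washout datasets
  as partial; verdicts should be read alongside the per-arm estimates.

## Problem sizes and numerical choices

The simulation studies run at desk scale: 100 recovery replicates per
ground truth (4 experiments × 60 design points each), 10,000 Dunnett null
layouts (vectorised with a single precomputed critical value), 200
label-permutation ANOVA replicates, and 0.005-log-unit exhaustive grids
for the optimizer cross-checks. A full test run takes about two minutes on
one CPU.

## Known limitations

* **Composite cooperativity is weakly identified for low-affinity,
  low-cooperativity NAMs.** For ground truth pK_B = 6.39 / log αβ = −2.38
  under the default design, the RSS profile in log αβ is nearly flat
  (~1 % over two log units): the probed B/K_B ≤ 25 never approaches the
  ~290-fold shift ceiling, and the plateau elevation that would otherwise
  pin αβ (~2.5 response units) sits below the replicate-mean noise. The
  estimator's log αβ scatter is then ~±1 log unit, and joint recovery
  within (±0.2, ±0.5) succeeds in only ~40–55 % of runs — an intrinsic
  identifiability limit of the design, not an optimizer failure (verified
  by profile likelihood and exhaustive grid search). The matching
  acceptance check is left failing by design; the high-affinity truth
  (pK_B 7.06 / log αβ −1.87) recovers at ~97 %.
* α = 0 is taken literally (the term is dropped from the occupancy
  bracket) while the composite αβ is retained; note that exact neutrality
  in this framework requires α = 1 *and* αβ = 1.
* No mixed-effects modelling across experiments, no Bayesian estimation,
  no model-comparison statistics beyond RSS/AIC.
* No vendor plate-file parsing; inputs are tidy CSVs with molar
  concentrations.
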