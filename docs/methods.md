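# Methods

## The screening problem

The 2016 WHO criteria for polycythaemia vera (PV) lowered the haemoglobin
(Hb) and haematocrit (Htc) thresholds that define erythrocytosis, so a large
fraction of routine blood counts — around 8–10% in hospital laboratory
populations — now formally qualifies for JAK2 p.V617F mutation testing, while
the mutation is found in well under 1% of that stratum.  `pvscreen`
implements a sequential two-step selection rule that restores a workable
pre-test probability:

1. **Step 1 (WHO 2016 criterion).** Select males with Hb > 16.5 g/dL or
   Htc > 49%, and females with Hb > 16 g/dL or Htc > 48%.  All comparisons
   are strict.
2. **Step 2 (myeloproliferation signs).** Among step-1 selections, test only
   individuals with neutrophils > 6×10⁹/L **or** platelets > 250×10⁹/L
   (rounded form; the raw derived cut-offs are 5.98 and 248.5).

The package contains everything needed to *derive* such a rule on a
development cohort, *validate* it on an independent cohort, and *audit* every
count along the way, exercised end to end on synthetic cohorts because no
patient-level data is distributable.

## Cut-off derivation

On the labelled development stratum (WHO-positive, DNA-extractable,
known-MPN cases set aside) each marker is first screened univariately:
pooled-variance Student t for the approximately normal red-cell indices,
Mann–Whitney U for the right-skewed cell counts, chi-square for sex.  Markers
with p < 0.05 proceed to ROC analysis.

Candidate thresholds are **midpoints between consecutive distinct observed
values**, plus one threshold below the minimum and one above the maximum so
that the degenerate operating points (sens 1/spec 0 and sens 0/spec 1)
always exist.  This convention is what produces half-unit cut-offs such as
248.5 from integer platelet counts.  At each threshold *t* (direction
"greater"): sensitivity = P̂(score > t | carrier), specificity =
P̂(score ≤ t | wild-type).  The optimal cut-off maximises the Youden index
J = sensitivity + specificity − 1; ties in J are broken toward the
higher-sensitivity (smaller, under "greater") threshold, matching a
screening test's sensitivity-first intent.

Two AUC routes are implemented independently and asserted equal to 1e-10:
trapezoidal integration of the empirical curve, and the rank statistic
(#{carrier > wild-type pairs} + ½·ties) / (n₊·n₋).  The identity
U/(n₁n₂) = AUC ties the Mann–Whitney module to the ROC module and is tested
across both.

The derivation direction is forced to "greater" for every marker by default,
mirroring how the original analysis evidently treated markers that run
*lower* in carriers (MCV, MCH show near-degenerate operating points there);
an `auto` mode that picks the direction with AUC ≥ 0.5 is available but off
by default.  The final rule's marker pair {neutrophils, platelets} is
configuration, not an automatic consequence of an AUC threshold.

## Statistical tests

* **Student t** (pooled variance, df = n₁+n₂−2) is the default because it is
  the variant that reproduces the published MCV (p = 0.033) and RDW
  (p < 0.001) p-values from their printed summaries; Welch is available.
* **Chi-square** for 2×2 tables is Pearson *without* continuity correction
  (reproduces the published sex-table p = 0.816); Yates is available.
* **Mann–Whitney U** uses midrank tie handling.  For n₁·n₂ ≤ 400 the exact
  conditional permutation distribution of U given the observed (possibly
  tied) values is computed by a counting dynamic program over doubled
  midranks, so identical samples give p = 1 exactly; larger samples use the
  tie-corrected normal approximation with continuity correction.  The
  approximation agrees with the exact distribution to ~0.017 in the worst
  case at group sizes of 5, shrinking with n.
* Quartiles use linear interpolation between order statistics (type 7).
  No multiple-testing adjustment is applied across the univariate battery,
  matching the original analysis; Holm correction can be applied by the
  caller if desired.

## Synthetic cohorts

The generator emulates the hospital-laboratory populations of the study:
two cohorts of ~15,000 blood counts, ~9% WHO-positive, with ~0.8% of the
WHO-positive stratum carrying JAK2 p.V617F.

* **Marginals.** Mean(SD)-reported markers (age, Hb, Htc, MCV, RDW, MCH,
  MCHC) are normal; median(IQR)-reported cell counts (WBC, neutrophils,
  platelets) are lognormal, matching the normal/non-normal split the
  original univariate analysis used.  Lognormal parameters come from an
  analytic inversion of the quantile function: μ = ln(median),
  σ = (ln q₇₅ − ln q₂₅)/(2·z₀.₇₅).  All marginals are truncated to the
  printed population min–max ranges by quantile mapping.
* **Carrier component.** Carriers' marker distributions reproduce the
  published carrier-stratum summaries.  Because those summaries describe
  carriers *within* the WHO-positive stratum, carriers are generated
  conditioned on the WHO criterion by rejection sampling (iteration-capped,
  with a degenerate-spec error if the component cannot satisfy the
  criterion).
* **Wild-type component.** Non-erythroid markers reproduce the published
  wild-type-stratum summaries (legitimate because the copula leaves them
  uncorrelated with Hb/Htc, so conditioning on the WHO criterion does not
  move them).  Population Hb/Htc distributions are *not* published; the
  sex-specific defaults — male Hb N(15.0, 1.3) / Htc N(44.8, 3.6), female
  Hb N(13.8, 1.2) / Htc N(41.7, 3.4) — are calibration values chosen once,
  analytically (bivariate-normal union probability at the WHO thresholds),
  so that ~9% of the population is WHO-positive and ~79% of that stratum is
  male, the two marginal facts the flowcharts report.  They are flagged as
  invented calibration values in the spec config.
* **Dependence.** A Gaussian copula with ρ(Hb,Htc) = 0.96,
  ρ(WBC,neut) = 0.90, ρ(MCV,MCH) = 0.85, zero elsewhere.  The copula
  preserves each marginal exactly (KS-tested); the Hb–Htc coupling is what
  makes the "Hb OR Htc" criterion behave realistically.  After the draw,
  neutrophils are clipped at WBC to honour the count hierarchy (<0.3% of
  draws).
* **Flags.** DNA-extraction failure is missing-completely-at-random at rate
  270/1271 ≈ 0.212; a carrier is an already-known MPN with probability
  5/13; both match the development flowchart.  The overall carrier
  probability is solved from the target within-stratum prevalence (0.8%)
  and the analytic WHO rate of the wild-type component.
* **Age** is generated (carriers older, SD a free parameter set to 18.3/20)
  but used by no rule, mirroring its non-significance in the original
  univariate analysis.

What the generator does **not** emulate: real analyser noise and rounding,
seasonal/diurnal case mix, correlated missingness (e.g. DNA failure linked
to sample age), secondary erythrocytosis subgroups, or JAK2-negative MPNs.
Passing tests therefore demonstrate that the *pipeline machinery* is correct
and calibrated to the printed group statistics, not that the derived
cut-offs would transport to any particular laboratory.

## Analytic AUC oracle

For parameter-recovery tests the package provides a closed-form AUC between
the two components: Φ((μ₊−μ₋)/√(σ₊²+σ₋²)) on the (log-)scale of the common
family, ignoring truncation.  Truncation is usually negligible, but for RDW
the carrier component N(15.3, 3.1) is cut at the population minimum of 10,
which shifts the true AUC by ≈ +0.03; an `exact=True` mode therefore
integrates P(X₊ > X₋) over the truncated marginals by quadrature and is the
oracle the recovery tests use.

## Two-phase pipeline

`run_phase1` applies the WHO criterion, drops DNA failures, "tests"
everyone remaining, sets aside known-MPN carriers, runs the univariate
battery and the ROC derivation on the tested stratum, and returns raw and
rounded (half-up to 0.5×10⁹/L for neutrophils, 10×10⁹/L for platelets)
step-2 rules.  `run_phase2` applies a frozen algorithm — it never
re-derives thresholds — and reports flow counts plus performance ratios:
yield among tested, prevalence in the WHO stratum and in the total cohort,
PPV per algorithm-fulfilling sample, NNT (tested per new carrier), and the
workload fraction (step-2-selected / WHO-positive).  Flow accounting is
exactly conservative: every record lands in one terminal bin and the bins
sum to the cohort size, asserted on every run.  Flow percentages are
half-up-rounded to one decimal, the convention that reproduces every printed
flowchart percentage from its printed counts.

## Problem sizes and numerical choices

Tests run the full two-phase study at the study's own cohort size
(n = 15,366 per phase) and parameter-recovery experiments on WHO-positive
strata of n = 10⁵.  At the study prevalence the development stratum holds
only ~5 new carriers, so locally derived cut-offs are noisy; recovery tests
therefore use balanced strata (5×10⁴ per group) for AUC — AUC is
prevalence-free — and a 200-seed regression envelope (central 95% interval,
computed once and frozen) for the platelet cut-off at the study prevalence.
Reproducibility is exact: one `numpy` Generator per cohort draw, seeded from
the spec or caller, no global state; identical spec+seed gives byte-identical
CSV output.

## Known limitations

* The published AUCs of 0.50/0.51 for MCV/MCH cannot be reconstructed under
  any direction convention tried (forced "greater" gives ≈0.30, "auto" gives
  ≈0.70); the published convention for reversed markers is unknown and is
  not reproduced.
* The exact cut-off values (5.98, 248.5, 13.05) belong to the original
  996-patient dataset and are not recoverable from desk-scale synthetic
  cohorts; the machinery that produces them (midpoint candidates,
  sensitivity-first Youden) is what is tested.
* The published carrier-stratum table is internally inconsistent (header
  n = 8 vs sex rows summing to 6); the generator makes no attempt to
  reproduce such inconsistencies.
* The Rumi-style comparator's female threshold is not stated in the source
  discussion; it is kept at the WHO value of 16 g/dL as a documented
  assumption.
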