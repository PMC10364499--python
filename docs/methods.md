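# Methods

`spdp_bench` implements two complementary ways of turning a multicentre
registry of minimally invasive spleen-preserving distal pancreatectomies
(SPDP) into benchmark values for ten intra- and postoperative outcomes, and
a synthetic registry generator that emulates the statistical structure such
an analysis assumes. This note records the models, the defaults and the
open design choices.

## The two benchmark statistics

**Achievable Benchmark of Care (ABC).** Computed on the *unselected* cohort,
one outcome and one approach stratum (laparoscopic/robotic) at a time. For a
binary outcome, each centre with at least one non-missing value contributes
its event count `e` and patient count `n`. Centres are ranked by the
*adjusted performance fraction*

    (e + 1) / (n + 2),

a shrinkage of the crude rate `e/n` toward 1/2 with weight `2/(n+2)` — the
posterior mean under a uniform prior — so that a 0/2 centre cannot lead the
ranking on noise. The benchmark is the pooled rate `Σe/Σn` of the shortest
ranking prefix whose patients reach 10% of the outcome's patient pool. Two
refinements are deterministic conventions of this implementation:

- *Ties.* Equal adjusted fractions are ordered larger-`n`-first, then by
  centre id; the prefix is extended through any centres exactly tied with
  its last member. The extension is what makes the selection invariant to
  duplicating every centre (a property the shortest-prefix rule alone does
  not have); on real data exact ties in `(e+1)/(n+2)` are virtually absent.
- *Zero-event exclusion.* For overall morbidity, major morbidity, conversion
  and clinically relevant POPF, a reported zero rate is read as
  under-ascertainment, and zero-event centres are dropped before ranking.
  By default the 10% threshold is then taken on the post-exclusion pool (the
  exclusion redefines the selection universe); `pool_basis="pre_exclusion"`
  switches to the full pool. For the other three binary outcomes
  (spleen-preservation failure, readmission, mortality) a true zero is
  attainable and zero-event centres stay in, so an all-zero prefix yields a
  0% benchmark.

For a continuous outcome (operation time, blood loss, hospital stay) the
mechanism is replaced wholesale: the ABC is the 10th percentile of the
per-centre medians. Alongside every benchmark the 25th/50th/75th percentiles
of the centre-level crude values are reported.

**Best-patient-in-best-centre (BPBC).** Computed on a *low-risk* cohort in
*volume-eligible* centres. Each centre contributes one value per outcome —
its median for continuous outcomes, its event proportion for binary ones
(the natural centre-level analogue of a median for a flag) — and the
benchmark cut-off is the 75th percentile of these values across centres,
unweighted (one centre, one vote), with the 25th percentile reported
alongside. The cut-off is an acceptability bound, not a best-achievable
value: for these lower-is-better outcomes a performer at or below the
cut-off is within benchmark. Because the ABC pools the best-ranked tenth of
patients while the BPBC takes an upper quartile across all eligible centres,
binary BPBC cut-offs sit at or above the corresponding ABC values; the test
suite asserts this ordering on synthetic registries.

**Percentile convention.** All percentiles anywhere in the package use
linear interpolation between order statistics (Hyndman–Fan type 7, numpy's
default). One consequence is accepted deliberately: the 10th percentile of
centre medians is not *exactly* invariant to duplicating every centre
(the interpolation index shifts); the deviation is bounded by one gap
between adjacent centre medians, and the tests assert that bound.

## Cohort filters

A patient is low-risk when none of ten exclusion criteria fires: extended or
multivisceral resection; previous major (bariatric/liver) abdominal surgery;
ASA grade ≥ III; BMI ≥ 35 kg/m² (boundaries inclusive); cardiac disease
(recent CHF, angina within 1 month, MI within 6 months, PCI or cardiac
surgery, atrial fibrillation); chronic renal failure (MDRD ≥ stage 3); COPD
with FEV1 < 80%; anticoagulant use (NOAC, VKA, clopidogrel); ≥ 2 oral
antidiabetics or insulin; age < 18. A record missing any field a criterion
needs cannot be shown low-risk; it is *indeterminate* and conservatively
excluded, counted separately in the attrition report.

A centre is volume-eligible when its mean annual caseload — records divided
by distinct contributing years — reaches 10/year (`volume_rule="mean"`,
reading "at least 10 annually over the contributing years" as an average);
`volume_rule="every_year"` demands every year individually reach the
threshold. Volume is necessarily computed on the SPDP registry itself, which
understates a centre's total minimally invasive distal pancreatectomy
activity; users holding full procedure counts should pre-filter centres
themselves.

Missing outcome data never remove a patient from the registry: each
outcome's pool is the per-outcome non-missing subset, so pool size plus
missing count always equals the record count.

## Group comparisons

Between-approach tables route categorical variables to uncorrected Pearson
χ² unless any expected cell count is below 5 (then Fisher's exact test, two
sided by summation of hypergeometric probabilities ≤ the observed table's),
and continuous variables to a two-sided Mann–Whitney U (exact null
distribution up to 20 per group without ties; tie-corrected normal
approximation otherwise). The uncorrected χ² choice is validated against
published 2×2 tables whose counts and P-values are both printed (0.811 for
the sex row, 0.230 for the preservation-failure row of the reference
cohort). Normality screening for presentation uses the Kolmogorov–Smirnov
test with Lilliefors critical values, since the normal parameters are
estimated from the sample; constant samples route to median/i.q.r. with a
warning. Significance is two-sided P < 0.050; values below 0.001 print as
"<0.001".

The type-I-error suite simulates identical groups (2×2 at n = 150 per group
with event probability 0.5; Mann–Whitney at n = 100 per group lognormal) for
1000 replicates and checks each rejection rate at 0.05 against a ±2
Monte-Carlo-SE band. Fisher's exact test is intrinsically mildly
conservative (long-run level ≈ 0.042–0.044 at this design, estimated with
20 000 replicates); the cell sizes are chosen large enough that it stays
within the band.

## Synthetic registry generator

The generator emulates a 2006–2019 European multicentre registry: defaults
are 32 centres with negative-binomial caseloads (mean 38, dispersion 1.5 —
a few large centres, many small ones), each contributing over a short random
span of years (mean ≈ 3.5), so a realistic mix of volume-eligible and
-ineligible centres arises. Approach is assigned per record from a
centre-specific robotic propensity (Beta around 0.227), so both strata exist
in most centres.

- **Centre quality heterogeneity** is beta-binomial: each binary outcome has
  a Beta law for the centre-level true rate, with means matching the
  reference cohort's marginals (conversion 0.082, overall morbidity 0.506,
  major morbidity 0.139, CR-POPF 0.182, preservation failure 0.182,
  readmission 0.132, 90-day mortality 0.007) and concentration a + b = 25
  (intraclass correlation ≈ 0.04). The Beta form keeps the BPBC recovery
  target analytic — with many patients per centre the binary cut-off
  converges to the law's 75th quantile — at the price of a heterogeneity
  level that published tables do not constrain; it is calibrated to be
  plausible (ABC < pooled median < BPBC ordering), not estimated.
- **Continuous outcomes** are lognormal with a per-centre normal location
  shift: operation time median 195 min laparoscopic with a fixed robotic
  log-shift to 262.5 min (σ = 0.39, centre sd 0.12); blood loss median
  100 ml (σ = 1.1, centre sd 0.25); stay median 7 days, robotic shift to 8
  (σ = 0.53, centre sd 0.10). Values are rounded to whole units and floored
  at clinically meaningful minima (30 min, 0 ml, 1 day).
- **Internal consistency** is enforced by hierarchical sampling: mortality ⊂
  major morbidity ⊂ overall morbidity (centre rates clipped to respect the
  ordering, grades drawn conditionally, deaths always grade V), and
  preservation method is splenectomy exactly when the failure flag is set,
  with the Kimura/Warshaw split per stratum (0.67/0.90 Kimura).
- **Covariates** are independent: age normal(57, 15) truncated at 18; BMI
  lognormal (median 25, σ = 0.18); female 0.62; ASA distribution giving
  80.5% grade I–II; exclusion-flag prevalences chosen so that the
  independent-flag product leaves roughly three-fifths of patients low-risk.
  Because flags are independent (real comorbidities cluster) and
  indeterminates are excluded, the realized low-risk share (~55–60%) runs a
  few points below the reference cohort's 62%.
- **Missingness** is MCAR per field, applied last (defaults 0.5% for
  covariates, 2% for outcomes). No MAR/MNAR mechanism is modelled — nothing
  in the reference material constrains one — so the pipeline's behaviour
  under informative missingness is untested by construction.

Everything is driven by one `numpy` `default_rng(seed)`; the same config and
seed reproduce the registry byte-for-byte, and the ground-truth object
(centre rates, centre shifts, caseloads) carries a config hash so truth and
registry cannot be mixed up across runs.

What passing tests on these registries show — and do not show: they verify
the estimators' invariances, their convergence to analytic targets under the
generator's assumptions, and the end-to-end plumbing. They cannot validate
the benchmark values against real surgical practice, where case-mix,
correlated comorbidities, informative missingness and calendar-time trends
all exist and are deliberately not modelled.

## Problem sizes used by the test and acceptance runs

Property suites use compact registries (8–10 centres, ~110 patients) across
200 seeds; the parameter-recovery experiment uses 30 centres × ~200 patients
with the low-risk exclusions switched off, so the filter is a no-op and the
analytic Beta quantile is the exact target (tolerance ±0.04, about 1.3
standard errors of a 75th percentile estimated from 30 centres); the null
calibration uses 1000 replicates. These sizes make the full suite run in
well under a minute while keeping Monte-Carlo error small relative to every
asserted tolerance.

## Known limitations

- Benchmarks carry no confidence intervals and centre rates are not
  risk-adjusted beyond the low-risk filter itself.
- The BPBC percentile is taken across centres; taking it across pooled
  patients is a defensible alternative the package does not implement.
- Whether the 10% ABC accumulation denominator should include zero-event
  centres is ambiguous; both variants are provided, post-exclusion is the
  default.
- The volume filter sees only SPDP records (see above).
- Presentation rounding (one decimal for percentages, half-up) matches
  clinical-table conventions; full precision is retained internally.
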