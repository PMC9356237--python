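# Methods

This note documents the statistical procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish.

## Dose conversion and intent

Fractionation schedules are compared on the biologically effective dose
scale of the linear-quadratic model, `BED = n·d·(1 + d/(α/β))`, with the
tumour α/β fixed at 10 Gy (`RadiobiologyParams.alpha_beta`). The curative
threshold of 95 Gy BED₁₀ is compared on the **unrounded** BED, so the
benchmark 7 Gy × 8 schedule (95.2 Gy) qualifies; a separate half-up
rounding helper produces the displayed integer values (95, 138). A course
is curative only when every treated lesion reaches the threshold *and* the
whole active tumour burden is ablated (all active metastases treated by
SBRT, or the remainder covered by another ablative modality). Missing dose
data raise an error rather than defaulting to palliative.

Central doses are quoted by scaling the prescription BED by the
prescription-isodose factor 1.5 (so a modal 138 Gy prescription is quoted
as a 207 Gy central BED). Note this is a *convention*: applying the LQ
formula to the 1.5× central physical dose per fraction (25.5 Gy × 3) would
instead give ≈ 272 Gy. The package deliberately reproduces the scaling
convention and does not "correct" it.

Local failure of a treated lesion is an increase of at least 20 % in its
longest diameter, boundary inclusive.

## Survival primitives

`survival_stats` implements the standard right-continuous conventions:
censored observations tied with an event time count as at risk; the KM
product runs over distinct event times; the median is the smallest event
time with S(t) ≤ 0.5 (`None` when never reached); Greenwood's variance
feeds a 95 % CI computed on the log-survival scale. The k-group log-rank
statistic uses the full hypergeometric variance–covariance quadratic form
(reducing to the familiar two-group O−E statistic for k = 2) with
upper-tail χ² p-values on k − 1 df and no continuity correction. The test
suite cross-checks both estimators against an independently coded oracle
and against lifelines, and verifies the nominal 5 % null rejection rate by
simulation.

## Cut-point search

"Greatest difference in TTR" is operationalised as the maximal log-rank χ²
over an exhaustive candidate grid: midpoints between consecutive distinct
observed values. A candidate is admissible only if every resulting group
holds at least `max(2, ⌊0.10·n⌋)` patients — 8 of 85 at the default
fraction — which blocks degenerate maximally selected splits while keeping
small-prevalence clinical strata (e.g. multiple CRC primaries) admissible.
Ties resolve to the smallest threshold(s), making the search fully
deterministic. Integer-valued variables therefore yield half-integer
thresholds, displayed in the ceiling style "<65 vs ≥65"; trichotomy
intervals are half-open and cover the whole real line, so no value falls
in a gap between intervals.

Missing values are deleted pairwise per variable at screening; the
complete-case restriction applies only at the scoring stage. No
multiple-testing or maximally-selected-statistics correction is applied to
the reported p-values — the selection inflation is real and is flagged in
the report output rather than corrected, because the screening rule being
reproduced is the uncorrected p ≤ 0.05 log-rank. Whether a variable is
dichotomised or trichotomised follows the caller's designation (default:
CEA trichotomised, the other four dichotomised).

## Scoring and signatures

Each selected variable maps the patient's value to the sub-score of its
interval (1 = greatest risk, i.e. shortest KM median TTR; interval risk
ranking uses the KM median with restricted-mean survival and interval
order as deterministic tie-breaks). The score is the arithmetic mean of
sub-scores; under the reference scheme (four dichotomies, one trichotomy)
the achievable grid is 1.0, 1.2, …, 2.2.

Signature formation enumerates all contiguous partitions of the distinct
score values and keeps those in which every pair of **adjacent** blocks
differs at p ≤ α by log-rank (α = 0.05 by default; an all-pairs mode is
available via `pairwise="all"`). Among admissible partitions the block
count is maximised; ties go to the partition with the largest minimum
adjacent χ², then to the lexicographically earliest boundaries. Adjacent
pairs rather than all pairs are the default because with ordered risk
groups adjacency is the binding comparison, and all-pairs testing at
n ≈ 80 makes four groups practically unattainable. If no two-block
partition is admissible, a single group is returned with a warning.

A caveat found during validation and worth knowing: the
"largest k with significant adjacent pairs" rule does not consistently
recover a planted block structure. Blocks that straddle a true boundary
are *mixtures* whose survival differs genuinely from their neighbours, so
off-boundary partitions — including ones with more blocks than planted —
can pass every adjacent test, and increasingly so as the separation
between planted blocks grows. On a faithful four-block structure
(study-size block masses, adjacent hazard ratio 2, n = 400) the exact
planted intervals are recovered in roughly half of replicates; the rest
are admissible alternatives with shifted boundaries or an extra split.
This is a property of the selection rule itself, verified against a
brute-force enumeration oracle, not an implementation artefact.

Patients missing any selected variable are excluded from scoring
(complete-case analysis). Group labels are Roman numerals ascending with
score; signature I (lowest scores) has the smallest benefit.

Stratified reporting merges the lower half of the signature groups (I–II
of four) versus the rest and splits each by treatment intent
(curative/palliative) or treated-site (lung-only/other), reporting KM
curves and medians per cell; empty cells are reported as empty.

## Synthetic cohort

The generator emulates the study cohort the scheme was derived from; its
defaults are the study conditions, not tuning knobs:

* n = 85 patients; exactly 6 records have one score variable masked
  (missing completely at random — the real missingness mechanism is
  unknown), leaving 79 complete cases.
* Age: truncated normal, mean 69.5, SD 10.5 on [40, 85], rounded to whole
  years (median ≈ 69). Sex: 54 % male.
* Performance status 0/1/2/3 with probabilities 0.67/0.20/0.12/0.01 —
  the published 1–2 mass (32 %) is split 20/12 so that the PS ≥ 2 stratum
  is large enough to be admissible in the cut-point search.
* CRC primaries 1/2/3 at 0.91/0.08/0.01.
* CEA (µg/L, integer): 65 % uniform on 1–4, 15 % uniform on 5–9, 20 %
  heavy lognormal tail `10·exp(N(2.2, 2.2²))` — overall mean ≈ 208 µg/L
  with a maximum in the reported range.
* Active metastases (1…5 at 0.25/0.28/0.30/0.12/0.05) and treated lesions
  per patient (1…4 at 40/24/16/5 of 85, hence 156 lesions in expectation)
  are drawn by a **comonotone coupling** (shared uniform through both
  quantile functions): both printed marginals are matched exactly and
  treated ≤ active holds by construction, at the price of a strong
  positive correlation between burden and treated count.
* 76 % of patients are lung-only; other patients get one extra-pulmonary
  lesion (liver/lymph-node/spine at 15:6:1). Fractionation mix per lesion:
  17 Gy × 3 (75.6 %), 15 Gy × 3 (9.6 %), 8 Gy × 5 (3.2 %), 10 Gy × 3
  (1.9 %), and the published "other" mass split between 7 Gy × 8 and
  6 Gy × 5 so that ≈ 89 % of lesions are ablative (≥ 95 Gy BED₁₀).
* Coverage flags: all mets treated iff treated = active; otherwise another
  ablative modality covers the rest with probability 0.53, chosen so the
  curative-intent fraction is ≈ 0.59.
* TTR: exponential proportional hazards (a Weibull shape is exposed but
  defaults to 1 — the data give no shape information), cumulative hazard
  `λ₀·exp(Σβ)·t`, with default log-hazard increments ln 2 (age < 65,
  PS ≥ 2), ln 2.5 (≥ 2 primaries, ≥ 3 metastases, CEA ≥ 10) and ln 1.6
  (CEA 5–9) on the reference risk intervals. The baseline λ₀ = 0.031 per
  month was calibrated once so the replicate-averaged KM median TTR is
  ≈ 7.2–7.3 months with ≈ 90 % of patients relapsing under administrative
  censoring uniform on 12–72 months.
* OS is a decoupled placeholder (exponential, median 36.5 months) so
  records are complete; it is not calibrated and not analysed. Per-lesion
  local-control outcomes are not simulated.
* Clinical variables are sampled independently of each other (apart from
  the burden/treated coupling); real cohorts are correlated, so passing
  recovery tests here says nothing about confounding between variables.

Sampling uses `numpy.random.Generator` (PCG64); a seed fully determines
the cohort across platforms.

## Problem sizes used in the checks

Recovery experiments use n = 400 patients and 100 replicates (cut-point
search) and the brute-force partition oracle up to 6 distinct scores;
calibration uses 500 replicates at n = 85; the null-calibration check of
the log-rank uses 1000 two-group replicates at n = 100 per group. When a
planted-effect experiment strips the other risk factors, its baseline rate
is re-anchored so the cohort median TTR stays ≈ 7.3 months — the planted
cohort remains on the study's outcome scale.

## Known limitations

* Maximally selected p-values are reported uncorrected (by design, see
  above); they overstate significance.
* The signature-selection rule recovers planted block structures only
  partially (see the caveat above); its output should be read as "a
  maximal significantly-separated grouping", not "the unique true one".
* At the spec'd study scale (n = 85) the screening step has limited power:
  low-prevalence variables (PS ≥ 2, multiple primaries) pass the p ≤ 0.05
  screen only in a fraction of synthetic replicates.
* Exact recovery of an integer-valued cut-point at moderate effect sizes
  (hazard ratio ≈ 2.5, n = 400) succeeds in ≈ 85–90 % of replicates, with
  the remainder landing one observed value away; near-certain recovery
  requires hazard ratios ≳ 4.
* OS and per-lesion local control are not modelled; no Cox regression,
  competing risks, nomograms or external-validation logic are provided.
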