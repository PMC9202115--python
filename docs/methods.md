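# Methods

## Scope and model of the audit

`randaudit` assesses the risk of selection bias arising from the
randomization process of a two-arm trial that stratified 1:1
permuted-block randomization by clinical center and onset-to-treatment
window (early = 0–90 min, late = 91–180 min). The audit treats the
realized allocation sequence and the baseline covariate table as data and
asks whether they are compatible with an intact randomization process.
It does not estimate what the "correct" treatment effect would have been
under perfect randomization; covariate adjustment can shrink the imprint
of selection on measured covariates, but selection on unmeasured
prognosis is invisible to every stage of this pipeline.

A participant counts as randomized only if an allocation was actually
issued, so `arm` and `time_stratum` are mandatory on every record.
Missing-data policy is complete-case per computation: a record is dropped
only from analyses that need the missing field, and each fit reports
`n_used`.

## Statistical components

**Allocation balance.** Per-stratum Δ = |nT − nC| with any Δ ≥ 1 counted
as a deviation from 1:1. This inclusive reading is the only one under
which "k of 16 strata deviate" is well defined without knowing block
boundaries; the threshold is exposed as an argument. Orthogonally to the
deviation flag, when the maximum block size b is known each stratum is
annotated with whether Δ > ⌊b/2⌋ — the largest imbalance a truncated
final block can explain, so anything beyond it requires a randomization
error. The bound is verified in the tests by exhaustive enumeration of
within-block allocation paths.

**Restriction rule.** The protocol constraint is that a center's
enrollment counts in the two time strata may never differ by 3 or more.
The default check compares final counts (what a reanalysis of closed data
can always do); a sequential mode replays enrollment order and reports
the first position at which the running difference reaches the threshold,
since the rule is intrinsically sequential and a final-count check can
miss transient violations. The sequential mode requires
`enrollment_index`, which the generator records as the global arrival
order (any ordering consistent within centers works).

**Cross-over direction.** For n cross-overs with k in one direction the
package reports both the exact binomial point mass C(n,k)·pᵏ(1−p)ⁿ⁻ᵏ and
the one-sided upper tail at p = 0.5. Both are printed because published
reanalyses sometimes print the point mass where a tail would be
conventional; for the audited trial's 21 of 22 the point mass is
5.245×10⁻⁶ and the tail 5.48×10⁻⁶ — the same conclusion either way.

**Imbalance scans.** Continuous covariates use the Welch t-test
(unequal-variance; a pooled-variance flag exists because the source
analysis said only "t-test"), binaries the χ² test with Yates continuity
correction, mirroring the audited reanalysis. Significance is α = 0.05
*inclusive* with no multiplicity correction, again mirroring the source;
the scan reports how many tests it ran so a reader can judge the
multiplicity. A summary-statistic Welch variant allows checking published
mean ± sd tables without raw data. Flagged imbalances are annotated with
the favored arm through a per-covariate prognostic direction map
(baseline NIHSS and old lesion volume: higher is worse; hyperintense
artery sign, abnormal CT, grey-white loss: presence is worse; prior
aspirin and small-vessel subtype: presence is favorable). Unknown
directions yield no annotation.

Note the continuity-corrected χ² is deliberately conservative: at
per-arm sizes near 160 its exact size is ≈0.02–0.04 for prevalences of
0.10–0.15 rather than the nominal 0.05. The test suite documents this —
the calibration check passes for the Welch-tested covariates and fails,
honestly, for the rarest binaries. Swapping in an uncorrected test would
calibrate the null at the cost of no longer being the procedure the
audit is meant to reproduce.

**Adjusted effects.** Each endpoint is dichotomized (mRS ≤ 1, Barthel ∈
{95,100}, NIHSS ≤ 1, GOS = 1; missing scores stay missing, never
unfavorable) and modeled by maximum-likelihood logistic regression
(IRLS via statsmodels GLM) of outcome on treatment plus the flagged
covariates; baseline NIHSS enters linearly, all other defaults are
binary indicators, old lesion volume is treated as a unitless
non-negative real since its units are not documented. Odds ratios carry
95% Wald intervals exp(β ± 1.96·SE) and two-sided Wald p-values.
Divergence (any |coefficient| > 15) is reported as complete or
quasi-complete separation naming the offending column, rather than
returning a meaningless estimate. The unadjusted fit (empty covariate
list) reproduces the 2×2 cross-product odds ratio to machine precision.
The early-stratum model is refit without the grey-white-loss variable
because the source data dictionary leaves open whether abnormal-CT
already subsumes it.

**RoB 2 domain 1.** The three signaling questions map to
low / some-concerns / high through an editable first-match rule table
transcribing the published algorithm: unconcealed allocation ⇒ high;
concealed + random sequence + unsuggestive baselines ⇒ low; unknown
concealment with suggestive baselines ⇒ high; everything else ⇒ some
concerns. The mapping is total over all 125 answer triples and
monotone (worsening any single answer never improves the judgement),
both verified exhaustively. Per-question "higher/lower risk" labels in
published tables are treated as annotation, not algorithm input.

## The synthetic world

The generator emulates the audited trial's stated design: 8 centers × 2
windows = 16 strata, target 624 participants, blocks drawn uniformly
from {2,4,6,8} (the real block sizes were never published; these are
plausible, not factual), the restriction rule enforced by excluding
arrivals that would push a center's running time-strata difference to 3,
and P(late window) = 322/624 matching the realized split.

Covariate defaults are anchored to the published baseline tables:
NIHSS ~ round(truncated N(15, 7²) on [0,42]), prior aspirin
Bernoulli(0.30), hyperintense artery 0.14, small-vessel subtype 0.15,
abnormal CT 0.45, grey-white loss 0.10, old lesion volume
Exponential(mean 1.5). Outcomes come from one shared latent score
β₀ + β_t·[treatment] + Σβⱼxⱼ + logistic noise, thresholded per endpoint,
so each endpoint is exactly a logistic regression with treatment
log-odds-ratio β_t (default log 1.7, the audited early-stratum effect)
and the four endpoints are positively dependent, as real stroke outcomes
are. The intercept 0.6 and covariate coefficients (−0.10 per NIHSS
point, ±0.3–0.5 for the binaries, −0.05 per lesion-volume unit) put the
control-arm favorable fraction near 25–30%, the neighborhood the trial
reported. Raw scores behind each dichotomy are representative values
(favorable mRS → 1, else 3, etc.) since the audit consumes only the
dichotomy.

Subversion mechanisms:

* **Foresight** (allocation-concealment failure): with probability φ the
  enroller knows the next allocation in the stratum schedule and
  excludes a candidate on the unfavorable side of the foresight cutoff
  when that allocation is treatment. The excluded arrival never enrolls
  and the allocation waits for the next candidate.
* **Directional cross-overs**: a scheduled treatment crosses to control
  with probability χ(1+δ) and a scheduled control with χ(1−δ), so the
  expected cross-over fraction is χ under 1:1 and δ = 1 reproduces the
  audited 21:1 one-way pattern at χ ≈ 22/624.
* **Unblinding**: a flag set with probability υ; it has no downstream
  effect in the generator and exists so audits can count it.

What a green test on this world does *not* establish: the generator
draws arrivals independently with identical covariate distributions
across centers and windows, has no secular trends, no differential
missingness, no measurement error in outcomes, and its selection
mechanism acts on a single measured covariate. Real trials can fail in
all of those ways; the synthetic world only establishes that the
pipeline detects the specific mechanisms it injects.

Everything derives from a single integer seed; identical config + seed
gives a byte-identical output table.

## Numerical and design choices

* α inclusive (p ≤ .05), Wald critical value 1.96, separation threshold
  |β| > 15, IRLS tolerance 1e-10, max 100 iterations.
* Binomial tail clamped to ≥ the point mass to absorb a one-ulp
  inversion at k = n.
* Degenerate scans (a constant covariate, an arm with < 2 complete
  cases) emit diagnostics instead of tests; a zero-margin 2×2 is an
  error; expected cells < 5 attach a warning.
* Monte-Carlo procedures that refit many replicates skip and count the
  rare quasi-separated fits (≈0.2% of replicates at stratum size ~310)
  rather than failing the whole study.
* In the bias-detection study, unadjusted and adjusted estimates are
  compared as means of log odds ratios pooled over both time strata.
  Two opposing forces act on the unadjusted estimator — non-collapsibility
  of the odds ratio attenuates it below the conditional β_t, while
  foresight selection inflates it — so at small φ its net bias is small
  and several hundred replicates are needed to resolve the ordering; at
  φ = 0.5 the inflation dominates decisively.

## Limitations

* Covariate adjustment is a sensitivity analysis, not a repair: the
  adjusted estimate is unbiased only if selection acted through the
  adjusted covariates.
* The adjusted (conditional) and unadjusted (marginal) odds ratios are
  different estimands; part of any unadjusted-vs-adjusted gap is
  non-collapsibility, not bias.
* The χ² continuity correction makes the scan conservative for rare
  binary covariates at per-stratum sample sizes.
* The reverse-propensity (Berger–Exner) test is not implemented; the
  block-bound annotation is the only schedule-aware check.
* Published-table reconstructions (counts from rounded percentages) are
  approximations and are labeled as such in the tests.
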