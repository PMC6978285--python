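# Methods

This note documents the models and procedures the package implements, the
default parameters and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions used
throughout.

## Instrument registries

The four adult mental-health instruments form a nested item architecture:
MH (396 items) and CMH (405) share a 330-item common core (66 items are
MH-only, 75 CMH-only); the ESP's 141 items are a subset of the common
core; the BMHS's 46 items are a subset of the ESP.  The Forensic and
Addiction supplements are represented by count-only placeholders (33 and
35 items).

Item wording is proprietary, so the shipped registry is a synthetic
namespace: named codes (`hallucinations`, `daily_decision_making`, …) for
every item a scale or CAP rule references, synthetic pads (`s_msi_001`,
…) for the rest.  Per-domain allocation follows the published domain
counts.  Those counts do not sum to the published instrument totals, so
the shortfall per instrument is padded with an `unclassified` domain; the
totals and overlaps above are asserted exactly at build time.  Three
internal inconsistencies in the published counts required documented
adjustments:

- the BMHS domain counts sum to 47 against a published total of 46; the
  administrative count is trimmed from 22 to 21;
- the ESP housing count (6) exceeds the MH housing count (5), which would
  break the subset structure; one ESP housing slot moved to the pad;
- the ESP's published functional-status count is 3, but the four-item ADL
  scale is listed as collected on the ESP; the ESP carries all four ADL
  items;
- the Addiction supplement's domain counts sum to 36 against a published
  total of 35; its administrative count is trimmed from 6 to 5.

Default item codings are 0–3 for symptom-frequency items, 0–4 for
ADL/IADL performance items and 0–1 for binary items, configurable per
item.  These make every published scale range arithmetically consistent
(four 0–3 items → 0–12; four 0–4 items → 0–16; four binary items → 0–4).
Missing data is *absence* from the response map — never an in-band code —
so the scale engine can distinguish "not assessed" from a true zero.
Dates are ISO-8601 calendar dates; the 90-day reassessment window uses
inclusive day counting.

## Summary scales

Sum scales add their component responses; any missing component makes the
score missing (no imputation).  An optional prorating mode scales the
observed mean up to the full component count (round half to even,
clipped), available only when at least half the components are observed —
conservative defaults because the instruments' own missing-data rules are
not public.

Two published range ambiguities are resolved in config: the Aggressive
Behavior Scale is coded 0–12 by default (four 0–3 items), matching the
distributions the scale is reported with; a 0–8 variant (components
capped at 2) ships as `aggressive_behavior_0_8`.  The Mania Scale's seven
components reach the published 0–20 maximum by coding
`sleep_problems_hypomania` 0–2; the IADL scale's seven components reach
0–30 by coding `meal_preparation` 0–6.  Both are recorded assumptions,
configurable per item.

The four decision-tree scales output an ordinal severity 0 (intact) to 6
(very severe).  The licensed tree algorithms are not public, so the
shipped trees are documented defaults over the published component lists:
binary comparisons (`item:` or `scale:` variables against cutpoints)
arranged so every leaf 0–6 is reachable, the all-best record scores 0 and
the all-worst record scores 6.  Trees are validated at load time (leaves
in range, variables declared, nested structure acyclic by construction)
and are replaceable via config without code changes.  A condition that
touches a missing item or an incomplete sub-scale yields a missing score.

`score_all` computes every scale applicable to the record's instrument
and omits the rest (never scoring them as 0): all 13 scales on MH and
CMH; the ESP omits CAGE, PAIN and IADL; the BMHS carries only the
Positive Symptoms Scale.

## CAP triggering

The 21 Clinical Assessment Protocols carry the published applicability
matrix and level counts: MH and CMH trigger 20 protocols each (the MH has
Support Systems for Discharge, the CMH Informal Support), the ESP
triggers Harm to Others, Suicidality and Purposeful Self-Harm, Self-Care
and Smoking; Support Systems for Discharge and Criminal Activity have one
trigger level, all others two.  Trigger thresholds are not published; the
default rules map each safety protocol onto its decision-tree scale
(level 2 at score ≥ 4, level 1 at ≥ 1) and every other protocol onto a
documented threshold over its nearest scale or item.  All rules are
config data, explicitly non-canonical, and monotone: raising any input
never lowers the triggered level.  Triggering rates use all assessed
records as denominator, with a completeness column reporting the share of
records whose rule inputs were fully observed.

## Psychometric procedures

*Cronbach's alpha* uses sample variances (n−1 divisor) throughout; this
matters only for small fixtures.  Complete cases only.  *Weighted kappa*
defaults to quadratic disagreement weights `((i−j)/(k−1))²` — the usual
choice for ordinal codes — with linear weights available; chance
expectation comes from the margin products.  The *c-statistic* is
computed by midranks, identical to exhaustive case–control pair counting
and to the area under the ROC curve.

*Convergent validity* fits a maximum-likelihood logistic regression of a
provisional-diagnosis flag on banded scale scores (indicator coding, the
zero band as reference), reporting exponentiated coefficients with Wald
95% CIs and the c-statistic of the fitted probabilities.  Complete-case
analysis with a logged listwise-deletion count; empty bands are dropped
with a warning; apparent separation (|coefficient| > 15 or a failed
Newton fit) is flagged on the result.  The exact adjustment sets behind
the published diagnosis models are not stated, so band configurations are
explicit and editable.

## Quality indicators

Admissions pair with the earliest follow-up — a reassessment within 90
days (inclusive) or a discharge assessment within the same window — one
pair per admission episode; admissions without an eligible follow-up are
excluded and counted, and episodes whose dates regress are skipped with a
log entry.  The two indicator families partition non-boundary pairs:
improvement (baseline > 0, event follow-up < baseline) and failure to
improve or worsening (baseline < scale max, event follow-up ≥ baseline).
A strict-worsening variant (follow-up > baseline) ships behind a flag.

The risk-adjustment method behind the production indicators is not
published; this package uses indirect standardization, the standard
approach for provider profiling: a pooled logistic model of the event on
baseline covariates (defaults: age band, sex, baseline score band,
homelessness) gives each stratum an expected rate (mean fitted
probability), and `adjusted = observed/expected × pooled`, clipped to
[0, 1] with a flag.  The reporting stratifier is always excluded from
the adjustment model — adjusting for the stratum itself would force every
stratified gap to zero by construction.  With an intercept-only (or
degenerate) model the adjusted rate equals the observed rate, flagged.

## Case-mix

The production inpatient classifier (47 groups, ~100 variables, an 8.4:1
CMI spread) is licensed and unpublished and is explicitly out of scope.
The module's contract is the surrounding machinery: a pluggable,
deterministic grouping function, a positive ratio-scale CMI table
(CSV-loadable), per-record assignment with unassignable records excluded
and counted, and mean-CMI summaries by assessment reason × period with
normal-approximation 95% CIs.  Percent change between two named periods
is `(later − earlier)/earlier × 100`, displayed to one decimal — an
asymmetric definition (the earlier period is always the denominator),
kept because that is how such trends are conventionally reported.  The
shipped toy grouper crosses a cognitive band (0 / 1–2 / 3–6) with a
positive-symptom band (0 / 1–5 / 6–12); its default nine-group CMI table
spans 0.5–4.2, reproducing the published 8.4:1 spread.

## Synthetic cohort generator

The generator exists because the real assessment data are proprietary; it
emulates the statistical *structure* those data are reported to have, not
their values.

The latent model is single-factor-per-scale with graded thresholds.  Each
person draws one standardized trait per scale; traits share a common
factor (default 30% shared variance) so scales correlate as clinical
scales do.  Item responses are the trait times a loading plus independent
noise, cut at fixed thresholds; the marginal latent is standard normal by
construction.  Loadings are solved from the Spearman–Brown relation
`α = k·r/(1 + (k−1)·r)` and then calibrated against the
discretized-normal correlation (a numeric root-solve over the bivariate
normal orthant probabilities), because thresholding attenuates
correlations — without the calibration, measured alpha undershoots its
target by 0.03–0.05 for typical 4-category items.  Default thresholds are
equal-quantile (roughly uniform category use); a zero-inflated preset
(60% of mass in category 0) is available to mimic the skew of real
symptom distributions.

Default conditions: cohorts of 5,000; 20% homeless with a +0.5 SD latent
shift on positive symptoms and smaller shifts on the safety-tree and
addiction latents (matching the reported direction of homeless/housed
severity gaps in clinical settings); per-scale alpha targets between 0.72
and 0.88, the range reported for these scales; diagnosis flags drawn from
logistic models on banded scale scores with band log-odds (0, 0.8, 1.4,
2.0) for psychosis on positive-symptom bands 0 / 1–2 / 3–5 / 6–12, and
(0, 0.5, 0.9, 1.4) for depression on depressive-severity bands 0 / 1–3 /
4–7 / 8–15 — band layouts mirroring the published convergent-validity
tables.  Rater B observes rater A's responses with a 10% chance of a ±1
category flip (clipped).  Follow-up latents are
`ρ·baseline − δ(group) + √(1−ρ²)·noise` with ρ = 0.6, δ = 0.8 for the
housed and δ = 0.4 for the homeless group, so the homeless group improves
less — the reported direction of the failure-to-improve gap.  One global
seed drives everything through documented stream splitting
(`default_rng([seed, stream_id])`), making cohorts byte-reproducible.

What the generator does **not** emulate: real category frequencies or
scale distributions (proprietary provenance), item-level missingness
mechanisms, facility/clustering structure, informative discharge timing,
or any real diagnostic mix.  Passing recovery tests therefore show that
the *procedures* are correct and well-calibrated under a known
data-generating process — not that real populations would produce any
particular value.

## Problem sizes and numerical conventions

Recovery analyses use cohorts of 5,000 (alpha, CAP rates), 10,000
(validity odds ratios) and 20,000 (risk-adjustment confounding removal) —
sizes at which Monte-Carlo error is comfortably inside the tolerances
being checked while the full suite runs in well under a minute of
simulation time.  Oracle-equivalence checks use ≥ 1,000 random small
instances per statistic against independent brute-force implementations.
Ties in the c-statistic count one half; bankers' rounding is used for
prorated scores; normal-approximation CIs use ±1.96 standard errors;
logistic fits use Newton iterations with a 200-iteration cap and fall
back to IRLS when Newton fails.

## Known limitations

Default trees, CAP thresholds and the toy case-mix grouper are structural
stand-ins, not clinical ground truth; conclusions about individual
patients must not be drawn from them.  The per-domain registry allocation
is a best effort against internally inconsistent published counts.  The
risk-adjustment covariate set is a conventional default, not the
production specification.  Alpha calibration matches the latent target to
the measured statistic only approximately when a scale mixes items with
different category counts (the calibration is per-item against its own
thresholds).
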