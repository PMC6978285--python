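# interrai-mh

A computable implementation of the interRAI adult mental-health assessment
suite for health-services researchers and quality-measurement teams who work
with standardized mental-health assessments but cannot redistribute the
proprietary instruments or their data.

The interRAI mental-health family comprises four instruments that share a
common item pool: the inpatient **MH** assessment (396 items), the
**CMH** community assessment (405 items, 330 in common with the MH), the
**ESP** emergency screener (141 items, a subset of the MH/CMH common core)
and the **BMHS** police screener (46 items, a subset of the ESP).  This
package makes that architecture executable end to end:

- **registry** — instrument/item definitions with the published totals,
  overlaps and per-domain allocation; record validation; JSON-lines and
  wide-CSV round-trip I/O.  Item wording is proprietary, so the shipped
  registry uses a synthetic item namespace that preserves every published
  structural fact.
- **scales** — the thirteen published summary scales: parallel-form sums
  (e.g. Positive Symptoms Scale 0–12, Depressive Severity Index 0–15, ADL
  0–16, CAGE 0–4) and 0–6 decision-tree severities (Cognitive Performance
  Scale, Risk of Harm to Others, Self-Care Index, Severity of Self-harm).
  Trees are data, loaded from config, so the documented default shapes can
  be replaced by licensed specifications.
- **caps** — Clinical Assessment Protocol triggering: 21 protocols with the
  published per-instrument applicability (MH and CMH trigger 20 each,
  differing only on informal supports; the ESP triggers the three safety
  protocols plus Smoking), each classifying a person into 0/1/2
  intervention levels through declarative rules.
- **psychometrics** — Cronbach's alpha
  `α = k/(k−1) · (1 − Σᵢ var(xᵢ)/var(Σᵢ xᵢ))`; weighted kappa
  `κ_w = 1 − Σ wᵢⱼOᵢⱼ / Σ wᵢⱼEᵢⱼ` with quadratic or linear disagreement
  weights; the concordance statistic
  `c = P(score_case > score_control) + ½·P(tie)`; and convergent validity
  via logistic regression of diagnosis flags on banded scale scores (odds
  ratios with Wald 95% CIs, model c-statistic).
- **quality** — the two mental-health quality-indicator families:
  *improvement* (follow-up < admission score, among persons scoring above
  zero at admission) and *failure to improve or worsening* (follow-up ≥
  admission score, among persons below the scale maximum at admission),
  paired over a 90-day/discharge window and risk-adjusted by indirect
  standardization (`adjusted = observed/expected × pooled` from a pooled
  logistic model on baseline covariates).
- **casemix** — per-diem case-mix machinery: group assignment, ratio-level
  case-mix indexes (CMIs), mean-CMI trend summaries with 95% CIs and
  percent change.  The production 47-group inpatient classifier is
  licensed and unpublished; a documented toy grouper with the published
  8.4:1 CMI spread exercises the machinery.
- **synth** — a synthetic cohort generator (single-factor graded-threshold
  latent model) producing ordinal items at a chosen internal consistency,
  group-dependent severity shifts, diagnosis flags with configured band
  log-odds, two-rater observations, and admission→follow-up pairs with
  group-dependent improvement, so everything above is testable without
  proprietary data.

## Worked example

```python
import numpy as np
import interrai_mh as m

registry = m.build_registry()           # MH 396, CMH 405, ESP 141, BMHS 46
scale_defs = m.load_scale_defs(registry=registry)

# a 5,000-person synthetic inpatient cohort
cohort = m.simulate_cohort(m.SimConfig(n_persons=5000, seed=1), registry, scale_defs)

comps = scale_defs["depressive_severity"].components
mat = np.array([[r.responses[c] for c in comps] for r in cohort])
print("alpha(depressive severity) =", round(m.cronbach_alpha(mat), 3))

# two-rater tables and admission -> follow-up records
rater_df, long_records = m.simulate_pairs(
    m.SimConfig(n_persons=3000, seed=2), registry, scale_defs)
table = m.agreement_table(rater_df, "hallucinations", 4)
print("weighted kappa(hallucinations) =", round(m.weighted_kappa(table), 3))

pairs, log = m.pair_followups(long_records, scale_defs, ["positive_symptoms"])
imp = m.compute_qi(pairs, "improvement").iloc[0]
print(f"improvement rate = {imp.rate:.3f} ({imp.numerator}/{imp.denominator})")
adj = m.risk_adjust(pairs, "failure", "homeless").set_index("stratum")
print("adjusted failure rate: homeless =", round(adj.loc[True, "adjusted_rate"], 3),
      "| not homeless =", round(adj.loc[False, "adjusted_rate"], 3))
```

Output:

```
alpha(depressive severity) = 0.849
weighted kappa(hallucinations) = 0.97
improvement rate = 0.704 (2036/2890)
adjusted failure rate: homeless = 0.477 | not homeless = 0.308
```

The generator was configured for a depressive-severity alpha of 0.85 and
the measured value is 0.849; the rater-noise model (10% chance of a ±1
category flip) yields a quadratic-weighted kappa of 0.97; about 70% of
simulated admissions with non-zero positive-symptom scores improve by
follow-up; and the homeless group — configured with a smaller treatment
improvement — shows the higher risk-adjusted failure-to-improve rate.

There is also a command-line interface over the same functions:

```bash
interrai-mh simulate --out cohort.jsonl --n 1000 --seed 1
interrai-mh score cohort.jsonl --out scores.csv
interrai-mh caps cohort.jsonl --out caps.csv --stratify homeless
interrai-mh casemix cohort.jsonl --out cmi.csv
```

Every artifact-producing run writes a `*.manifest.json` with the command,
parameters, seed and record counts needed to re-run it exactly.

## Scope notes

Proprietary content is out of scope by design: item wording and coding
manuals, the licensed decision-tree algorithms and CAP trigger thresholds
(documented defaults are shipped in their place and are replaceable via
config), the 47-group inpatient case-mix classifier, and the child/youth
and non-mental-health instruments.  See `docs/methods.md` for the models,
default parameters and limitations.
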