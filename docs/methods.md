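# Methods

## Model overview

`adrrisk` treats every aggregate risk as the probability of at least one
success among independent, non-identically distributed Bernoulli trials —
`1 − ∏(1 − pᵢ)`, the complement of the Poisson-binomial mass at zero. The
independence assumption is applied three times: across the drugs that can
cause one ADR (frequency score), across the two severe outcomes given an ADR
(severity score), and across the clinically relevant ADRs of a patient
(total, SOC and outcome-specific scores). It ignores pharmacokinetic
interactions, shared causal pathways between ADRs, and dose/duration
effects; the scores are therefore screening quantities, not causal
estimates.

The severity probabilities `Pr_hosp(ADR j)` and `Pr_mort(ADR j)` are the
patient-tailored part. They answer: *if* this patient on this therapy
develops ADR *j*, how likely is the episode to end in hospitalization, or in
death/life-threat? They are supplied by two independently trained classifier
ensembles over the same feature vocabulary.

## Feature encoding

One training instance is one report: `[age/100, male indicator, drug
indicators, pathology indicators, ADR indicators]`, with the report's full
ADR set multi-hot encoded. At scoring time the query instance carries a
single ADR bit, so the model is asked one ADR at a time. Age is scaled by
100 so it shares the indicators' [0, 1] range; gender is encoded male = 1.
Vocabularies are lexicographically ordered and serialized with the model, so
encodings are stable across sessions.

The six comorbidity predictors are fixed: Cardiac failure, Diabetes
mellitus, Hepatic insufficiency, Hypertension, Renal insufficiency,
Thrombosis risk factors.

## Ensemble configuration

Each outcome model is an ensemble of five scikit-learn `MLPClassifier`s
with one hidden layer of 40 logistic units, at most 500 iterations, loss
tolerance 0.1 and logistic activation. The members share hyperparameters and
differ only by random seed (initialization and batch shuffling); bootstrap
resampling per member exists behind `EnsembleConfig.bootstrap` but is off by
default, as seed diversity alone already de-correlates the members. The
ensemble probability is the unweighted arithmetic mean of the members'
class-1 probabilities — with no stated reason to weight members, the mean is
the variance-reducing default.

The mortality training set is rebalanced before fitting by random minority
oversampling: rows of the minority class are duplicated (sampling with
replacement, seeded) until each class reaches its configured target; the
default `"balance"` raises every class to the majority count. The
hospitalization model is trained on the raw, mildly imbalanced data.
Oversampling deliberately trades probability calibration for class balance:
the mortality model's probabilities are shifted upward relative to the true
conditional risk (its Brier score and reliability slope reflect this), while
the hospitalization model stays calibrated. Calibration-recovery checks
therefore target the hospitalization ensemble.

## Scoring rules and numerical choices

- The severity threshold is inclusive: an ADR with severity exactly 0.7
  counts as clinically relevant.
- Ranking ties are broken lexicographically by Preferred Term, making ranked
  output deterministic.
- Complement products are accumulated over factors sorted ascending; at the
  magnitudes involved (hundreds of terms in [0, 1]) double precision is
  ample and no log-space transform is needed.
- The outcome-specific risks use `1 − ∏(1 − F_j · Pr_outcome(j))` over the
  severity-passing set — the natural outcome-specific analogue of the total
  score. It is isolated in one function (`cumulative_outcome_risk`) so an
  alternative stratification rule could be swapped in.
- Degenerate inputs: an empty frequency list scores 0; a patient whose
  known drugs list no ADRs gets an all-zero profile; queried drugs missing
  from the knowledge base warn and contribute nothing, and only an entirely
  unknown drug list is an error.

## Knowledge-base handling

Drug names are matched case-insensitively and stored lower-cased; Preferred
Terms are matched case-insensitively and stored sentence-cased, since source
capitalization is inconsistent across databases. Frequencies may be given as
proportions or with a trailing `%`. Duplicate (drug, PT) rows — including
collisions created by term harmonization — are merged, by default keeping
the maximum (worst-case) frequency; a mean policy is available. The
harmonization map must be idempotent (no canonical term is itself a
synonym), which rules out cycles and makes application a fixed point.

## The synthetic-data generator

The generator emulates the *shape* of a label-derived side-effect table and
a cleaned spontaneous-report corpus, with a fully known generative law:

- knowledge base: each drug lists 2–8 ADRs; frequencies are Beta(0.9, 9)
  draws (mean ≈ 0.09, right-skewed like label frequencies); each ADR belongs
  to exactly one SOC and every SOC is non-empty.
- reports: age ~ Normal(60, 15) truncated to [18, 100] (rejection-sampled,
  rounded to years); gender a fair coin; 1–8 drugs per report uniformly
  without replacement; each of the six comorbidities an independent
  Bernoulli(0.1); each (drug, ADR) pair fires Bernoulli(table frequency);
  outcomes are Bernoulli(logistic(linear predictor)) with additive
  coefficients for scaled age, gender, each drug, pathology and ADR.
- reports with no fired ADR are rejected and redrawn in full rather than
  force-assigned one, keeping per-drug frequencies interpretable; the
  resulting conditioning bias is small whenever the per-report chance of
  zero ADRs is small, and the frequency-convergence test constructs exactly
  that regime (an always-firing anchor ADR).
- a single seeded generator stream is consumed in a fixed order (age,
  gender, drugs, pathologies, ADR fires, outcomes per report), so corpora
  are pure functions of (knowledge base, spec, n).

The "moderate" default effect sizes draw drug/ADR/pathology coefficients
from N(0, 0.6)/N(0, 0.8)/N(0, 0.5), set age slopes of +2 (hospitalization)
and +3 (mortality) per scaled-age unit, gender effects of +0.3/+0.5, and
intercepts of −1.5/−3.5 — giving roughly 45% hospitalization and 20–25%
mortality prevalence, i.e. the mild and the ~1:4 imbalance regimes typical
of spontaneous-report outcome flags, with a Bayes ROC AUC near 0.8.

What the generator does *not* emulate: duplicate reports, missing data,
reporting biases, drug-drug correlations in prescribing, or non-logistic
outcome mechanisms. Passing the recovery tests shows the pipeline can learn
a well-specified logistic signal at realistic prevalence and dimensionality;
it does not certify performance on real spontaneous-report data.

## Validation choices

- Class predictions use `probability ≥ threshold` with threshold 0.5 by
  default (configurable).
- Precision and recall are reported as absent (`None`) when their
  denominator is zero, and F1 is then absent too, rather than silently 0.
- ROC AUC is the Mann–Whitney probability with ties counted ½ (computed via
  scikit-learn; verified in tests against an all-pairs counting oracle).
- Reliability curves use 10 equal-width bins on [0, 1], right-open except
  the last, empty bins omitted; the reliability slope is the unweighted
  least-squares line through the non-empty bin points.
- The hold-out split takes `round(n · fraction)` records (banker's
  rounding) after a seeded uniform shuffle, without stratification.

## Problem sizes

The test suite and the acceptance script run the full pipeline at 40 drugs /
120 ADRs / 8 SOCs with 20 000 reports and an 80/20 split — large enough for
the hold-out metrics to sit within a few thousandths of their asymptotic
values, small enough to rerun casually; unit tests use a 12-drug / 30-ADR
base with 1 500 reports.

## Known limitations

- Drug doses, treatment duration and pharmacokinetic interactions are out of
  scope; only additive (pharmacodynamic-style) co-exposure effects are
  representable.
- The per-report (multi-hot ADR) training instance is an interpretation
  choice; per-ADR triad instances would multiply the training set by the
  mean ADR count per report and change the implied conditioning. The scoring
  query, with its single ADR bit, is slightly off-distribution relative to
  the training instances; the calibration tests bound the practical effect.
- Oversampling-induced upward bias in mortality probabilities propagates
  into severity scores; users comparing hospitalization and mortality risks
  should treat the mortality figure as deliberately conservative.
- The severity threshold (0.7), oversampling policy, and ensemble size are
  configuration, not fitted quantities; no hyperparameter search is
  performed.
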