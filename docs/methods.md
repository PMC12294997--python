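# Methods

This note records the modelling choices behind scrubmatch: what is computed,
why it is computed that way, what the synthetic data does and does not
emulate, and where the design was genuinely open.

## Compatibility score

The matching engine needs a totally ordered notion of patient–provider fit.
We use a convex combination of four terms, each in [0, 1]:

| term | definition | weight (default) |
| --- | --- | --- |
| constraint | 1 if the provider stocks every required resource in quantity | 0.4 |
| specialty | Jaccard similarity of condition tokens vs specialty∪service tokens | 0.3 |
| feature | cosine similarity of optional numeric vectors, clamped at 0 | 0.2 |
| capacity | min(1, capacity / (6 − urgency)) | 0.1 |

plus a **gate**: if any required resource is missing or under-stocked the
score is exactly 0. The gate encodes the operational reading of eligibility
criteria — a cardiologist without an ECG machine is not "70% compatible"
with a patient who needs one; they are not an option. It also makes the
additive capacity term consistent: without the gate, any provider with
capacity ≥ 1 would score positively against every patient regardless of
feasibility.

Choices worth stating:

- **Tokenization** is lowercase + split on non-alphanumerics, no stemming.
  Deterministic and dependency-free; "Chest-Pain" and "chest pain" agree,
  "chest" and "chests" do not. Semantic normalization of facility-specific
  terminology is explicitly out of scope.
- **Urgency demand** is 6 − urgency, so an ESI-1 patient "demands" headroom
  of 5 slots and an ESI-5 patient demands 1. The term rewards providers with
  slack relative to how urgent the patient is; min(1, ·) caps it so large
  capacities don't dominate.
- **Cosine clamping** at 0: anti-correlated feature vectors mean "no
  similarity", not negative compatibility; the score must stay in [0, 1].
- **Missing inputs degrade, never fail**: absent numeric vectors contribute
  0; an empty token intersection contributes 0. Profiles in practice are
  heterogeneous, and a missing field should not crash a matching run.
  Mismatched vector *lengths* are an error, since that indicates
  inconsistent featurization rather than missing data.
- Weights are validated to sum to 1 within 1e−9 and are fully configurable;
  the defaults order the terms by how defensible they are clinically
  (feasibility > specialty fit > learned features > slack).

## Preference derivation and deferred acceptance

Ranks use competition ranking — rank 1 plus the count of strictly better
scores — so equal scores share a rank, and with score-derived preferences
equal rank implies equal score. The acceptance rule ("displace the worst
assignee iff the proposer has strictly lower rank, or equal rank and
strictly higher score") therefore retains the incumbent on genuine ties,
which is the deterministic choice; the score tie-break can only change an
outcome when preference lists are supplied explicitly and disagree with the
scores. Both paths are implemented and tested.

Two algorithmic details differ from the classic textbook loop:

1. **Exhaustion**: a patient who has proposed to every provider and remains
   unmatched is removed from the unmatched pool and reported. Without this,
   over-subscribed instances (|P| greater than total capacity) never
   terminate. With it, every run satisfies proposals ≤ n·m, and the reported
   `unmatched` set together with `pairs` partitions the patients.
2. **Capacities**: a provider holds an assignee *set* of size ≤ capacity and
   compares proposers against its current *worst* member (highest rank, then
   lowest score, then largest id — all deterministic). Capacity 1 recovers
   the one-to-one algorithm exactly.

Determinism throughout: the unmatched pool is processed in ascending patient
id order; provider ties at equal rank and equal score fall to ascending
provider id; score comparisons are exact floating point with no epsilon.
Identical inputs give bit-identical outputs.

**Stability checking** is a brute-force scan over all (p, r) pairs using the
same strict-preference relation as the algorithm: p must strictly prefer r
to its assignment (an unmatched patient prefers anyone), and r must have
spare capacity or strictly prefer p to a current assignee. The **enumeration
oracle** lists every stable one-to-one assignment for instances up to 8×8;
it only enumerates assignments saturating min(n, m) pairs, because a partial
assignment leaves an unmatched patient and a free slot, which always block.
The test suite uses it to confirm both membership and patient-optimality of
the deferred-acceptance output — the oracle never shares code with the
algorithm beyond the blocking-pair definition.

**Dynamic re-matching** is a full recomputation from updated profiles.
Incremental maintenance of a stable matching under profile churn is a
different (and much harder) problem; at the cohort sizes targeted here
(hundreds per side, O(nm) proposals) recomputation is cheap and keeps the
invariants trivially intact.

## Scheduling state machine

A tick applies S(t+1) = F(S(t), R(t)) and increments t. The six stages run
history-first; composition is right-to-left over the stage list, matching
the functional notation. Every stage short-circuits the NoReq marker by
construction (the wrapper, not each stage body, enforces it), which makes
"empty ticks change nothing" a structural property rather than a
per-stage obligation.

The default stage suite is deliberately rule-based:

- *history* looks up and bumps a visit counter in the registry;
- *vital* computes acuity with a trained triage model if configured, else a
  coarse threshold screen (count of grossly abnormal vitals, sharpened by
  severe pain) — a placeholder priority heuristic, not a validated ESI
  algorithm;
- *profile* builds a PatientProfile from the complaint and acuity;
- *prognosis* maps complaint tokens to required resources through a
  configurable rule table; an unmatched complaint yields an empty resource
  plan and a logged warning rather than an error;
- *logistic* shortlists the top three providers (configurable) with free
  slots by compatibility score, ties broken by provider id;
- *appointment* runs deferred acceptance restricted to the shortlist, with
  capacities set to each provider's free-slot count, and writes the patient
  into the first empty slot. A patient already holding a slot is not
  scheduled twice; if every provider is full the request is reported
  unmatched and the schedule is untouched.

Slots have no time-of-day semantics — "first empty slot" is the whole
calendar model. Cancellations, no-shows, referral dependencies and
human-in-the-loop overrides are out of scope.

## Triage regression

Nine regressors are supported (linear, ridge, lasso, random forest,
gradient boosting, AdaBoost, bagging, extra trees, histogram gradient
boosting), instantiated from scikit-learn with library-default
hyperparameters unless overridden; the effective configuration, seed and
feature order are recorded with every fitted model. The feature order is
fixed (temperature, heartrate, resprate, o2sat, sbp, dbp, pain) so
serialized models cannot be silently fed permuted columns.

MAE, MSE and R² are computed directly from their definitions rather than
via library calls — the library versions serve as an independent oracle in
the tests. R² with constant truth is reported as NaN with a warning: TSS is
0 and the quantity is undefined; coercing it to 0 would make a useless
predictor on flat data look as good as the mean predictor on varying data.

Cross-validation uses a shuffled k-fold split (k = 5 default) with the
shuffle seeded, and the *same* folds for every candidate model, so the
leaderboard differences are attributable to the models alone. Selection is
by lowest mean MAE, with MSE, then R², then model name breaking ties.
Rounding predictions onto the ESI scale (round half away from zero, clip to
[1, 5]) is a presentation bridge, not part of the fitted model.

## Evaluation metrics

CR, TCS and TC are ratios over explicitly annotated logs; the package does
the arithmetic and the threshold gating, never the judging. TCS's alignment
score is keyword coverage — the fraction of configured required keywords
whose tokens all appear in the output — falling back to the Jaccard
similarity of task/output token sets when no keywords are configured. This
is a deliberate, fully reproducible stand-in for semantic alignment
judgment; the log formats accept annotations from any upstream judge, so
the arithmetic layer is shared either way. The gate threshold τ defaults to
0.7; nothing in the problem pins this value and it is exposed everywhere it
is used. Gates are inclusive (metric ≥ τ). Budget checks verify recorded
evaluation counts against their k·m caps; no refinement loop is
implemented, because no stopping rule short of the cap is defined.

## Synthetic data

The generators exist to make every claim measurable against planted ground
truth; all draw from `numpy.random.default_rng(seed)` and are bit-stable
across runs and platforms.

**Vitals.** Each of the seven vitals is uniform over a broad plausible
range (e.g. o2sat 70–100%, sbp 80–200 mmHg). Latent acuity is

    g = 5 − 4·σ(gain·(Σ_i w_i·|x_i − mid_i|/scale_i − center))

with per-vital midpoints at textbook normals, scales of roughly one
"clearly abnormal" deviation, weights summing to 1 (o2sat and heart rate
weighted highest), gain 4 and center 0.83 — the center equals the empirical
mean of the weighted deviation sum under these ranges, so generated acuity
centers near ESI 3 and spans ≈ (1.1, 4.8). The observed label is
clip(g + N(0, σ), 1, 5), and g ships alongside as `g_true`. Because
E|N(0, σ)| = σ·√(2/π), noise recovery is checkable: at σ = 0.5 the
cross-validated MAE of a good model should approach 0.399, measured on
records whose 3σ noise band avoids the clip boundary (training still uses
all records; only the measurement excludes them, since clipping biases
|label − g| downward near the bounds).

What this does *not* emulate: real triage-table vitals are correlated
(shock is tachycardic and hypotensive together), non-uniform, missing-prone,
and their mapping to recorded acuity is noisy in decidedly non-Gaussian
ways. Passing recovery tests shows the pipeline recovers *this* generative
family at the stated noise, not that any model achieves a particular error
on clinical data.

**Planted cohorts** (capacity 1, n ≤ m): patient i receives its planted
provider's unique specialty token, an exclusive required resource only that
provider stocks, a matching one-hot feature vector, and urgency 5 (so the
capacity term is equal across providers). The planted pair scores exactly
1.0; every other provider fails the resource gate and scores 0 for that
patient, so the margin is 0.9 — far above the 0.2 the recovery tests
require — and mutual-first preferences make the planted pairing the unique
stable matching. Unplanted cohorts draw conditions, specialties, resources
and capacities (1–3) from small fixed pools.

**Request streams** are Bernoulli(arrival_prob) arrivals per tick with
fresh vitals and a complaint from the condition pool; **evaluation
fixtures** are constructed backwards from requested metric fractions so the
measured CR/TCS/TC must round-trip exactly.

## Numerical and degenerate-input choices

- Scores are capped at 1.0 after summation to absorb float drift in the
  convex combination; no other epsilons exist anywhere.
- Jaccard of two empty token sets is 0 (no evidence of fit), not 1.
- An empty task output scores TCS = 0 without error; empty statement or
  tool-call logs are errors (a ratio over nothing is meaningless).
- Matrix validation rejects non-finite or out-of-range scores at
  construction, so downstream code never defends against them.

## Problem sizes

The shipped test and acceptance runs use: 200 random cohorts up to 50×50
with mixed capacities for stability; 500 instances up to 6×6 against the
enumeration oracle; 100 planted 6×6 cohorts; 1000 random states for
empty-tick identity; 100 constructed evaluation fixtures; and 5000-record
vitals tables for 5-fold CV recovery. These sizes give the properties room
to fail (tie handling, displacement chains, clip effects all occur) while
keeping a full run in well under a minute; the matching engine itself
handles the "hundreds per side" regime the O(nm) bound targets.

## Known limitations

- The compatibility function is a fixed rule-based instantiation; no
  learned similarity metric, no semantic normalization of terminology.
- One-to-many matching only on the provider side (capacities); no
  many-to-many, no truncated/unacceptable preference lists, no incremental
  re-matching.
- The scheduler has no calendar semantics, cancellations or overrides.
- The rule-based acuity screen is a heuristic placeholder, not a clinical
  instrument; the regression models are only validated against synthetic
  generative truth.
- Evaluation metrics require pre-annotated logs; the package never judges
  relevancy or alignment itself.
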