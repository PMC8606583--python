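# Methods

## Model

`orrisk` builds an associative classifier whose rules are single-item
associations *item ⇒ in-hospital mortality* quality-scored by the odds
ratio rather than the classical support/confidence metrics, so that rare
but strongly associated items (rare diseases, small subgroups) can enter
the model. The pipeline is:

1. **Itemset transformation.** Every case becomes a set of
   (variable type, code) items plus a binary died/survived outcome.
   Duplicated events collapse; no case is excluded, including cases with
   empty item sets. Codes are compared as exact, case-sensitive strings
   with no whitespace normalisation: near-duplicate codes surfacing as
   separate rules with very different ORs is a *feature* — it exposes data
   inconsistencies that would otherwise be invisible among ~10⁵ variables.
2. **Mining.** One 2×2 table per distinct item; OR = (a·d)/(b·c). Items
   with a zero cell are discarded outright (no Haldane–Anscombe
   continuity correction): an OR of 0 or ∞ is treated as unestimable, not
   as evidence.
3. **Filtering.** Two-sided test of OR = 1 by the normal approximation of
   the log odds ratio, z = ln(OR)/SE with the Woolf large-sample standard
   error SE = √(1/a+1/b+1/c+1/d). Rules are kept iff p < p_max (strict,
   matching "below"); with Bonferroni correction the threshold is
   p_max / m where m counts the tests actually executed, i.e. candidates
   surviving the zero-cell discard — not the full variable universe. The
   configuration p_max = 0 keeps exactly the rules whose p-value
   underflows to floating-point 0; it is therefore insensitive to the
   Bonferroni flag by construction. Exact underflow depends on the
   floating-point environment, so p_max = 0 rule counts are reproducible
   on one platform but only approximately portable.
4. **Prediction.** A case's score is the *arithmetic* mean of the ORs of
   its applying rules (the published worked example pins this down:
   (0.58+0.80+0.57+0.73+0.50)/5 = 0.636 ≈ the printed 0.64, and the
   nine-rule mean 5.3278 matches the printed 5.328; a geometric mean
   would not). Ties at the boundary classify high-risk (the decision
   function uses ≥). A case matching no rule receives the neutral score
   1.0 — the no-association OR — and is low-risk for any δ > 1; the
   source method leaves this case unspecified, so the neutral-score
   policy is this package's documented gap-fill, and the CLI logs each
   occurrence.

## Evaluation protocol

Repeated simple random 90/10 train/test splits (unstratified, matching the
protocol's wording; with 1.79% mortality a degenerate split that leaves a
side single-class is flagged invalid rather than dropped). Per repetition
candidates are mined once on the training split and re-filtered for every
cell of the grid {0} ∪ {10⁻ⁿ: n = 0…10} ∪ {0.05} × {Bonferroni on, off}
(26 configurations; 10 repetitions by default). AUC uses the Mann–Whitney
rank statistic with ties counted ½ — ties are frequent because scores are
means over a small shared rule pool — and equals the trapezoidal area
under the empirical ROC curve. The decision boundary is the score
threshold maximising the Youden index **on the training split** (the
protocol does not name the split; calibrating on training data avoids
leakage), with ties broken toward the smallest optimal threshold;
accuracy/sensitivity/specificity are then measured on the test split, as
is the mean number of applying rules per case. Repetition aggregates
report mean ± standard deviation.

## Synthetic populations

The generator emulates the statistical structure of a large
emergency/critical-care population, not its clinical semantics:

- outcome ~ Bernoulli(0.0179), the base in-hospital mortality rate of the
  emulated population;
- five demographic families (gender 2, ethnicity 6, insurance 3,
  language 2, marital status 5 categories — 18 minimal-class items) in
  which each case draws exactly one category per family. Death-side
  category probabilities reweight the survivor distribution,
  p_k ∝ w_k q_k, with mild weights (0.47–4.59) echoing published
  demographic effect sizes; because categories share one multinomial the
  *realised* per-category OR differs from the raw weight and is reported
  exactly in the truth table;
- clinical items (diagnosis/prescription/procedure/service/ward) occur
  independently given the outcome, with log-uniform survivor prevalences
  (mostly rare, 0.002–0.4 depending on type) and planted ORs spanning
  0.05–50 (80% harmful), fixed deterministically per scale;
- for an independent item, prevalence among deaths is
  p = ρq/(1−q+ρq), so the population 2×2 table recovers the planted ρ
  exactly in expectation — this makes parameter recovery a clean test
  surface;
- `small` ≈ 5,000 cases / ~120 items; `medium` ≈ 50,000 cases / ~1,020
  items. All randomness flows from one seed through a hierarchical
  `SeedSequence` (outcome stream, then one stream per variable/family),
  so adding a variable leaves the other draws unchanged.

Conditional independence given the outcome is exactly the regime in which
per-item ORs are the correct signal; real clinical data violate it
(comorbidity structure, correlated prescriptions), so passing tests here
demonstrate correctness of the machinery and consistency of the
estimator, not clinical performance. Headline AUCs on synthetic data
(full ≈ 1.0, minimal ≈ 0.78 at medium scale) accordingly overstate what
correlated real data yield.

## Numerical and design choices

- **Problem sizes.** Tests and the acceptance script run at small
  (5,000-case) and medium (50,000-case) synthetic scale, with 100,000
  cases for single-variable recovery checks — sizes chosen so the
  large-sample normal approximation is exercised while a full run stays
  in the minutes range on one CPU.
- **Specificity arithmetic.** The ROC curve computes specificity as
  tn/N rather than 1 − fp/N; the two differ by one ulp, which matters
  when detecting exact Youden-index ties.
- **Split seeds** derive as base_seed + repetition; every public entry
  point taking randomness takes an explicit seed.
- **Serialisation.** Model JSON is canonical (fixed key order, rules
  sorted by type then code) so write→read→write is byte-identical.
  Rules transcribed from published listings carry p_value 0, no
  contingency table, and a `provenance.transcribed` marker so they are
  never mistaken for mined output.
- **Validation.** Degenerate inputs fail loudly: single-class case
  collections, p_max outside [0,1], classification without a calibrated
  boundary, unknown variable types, conflicting outcomes within one case.

## Known limitations

- Single-item antecedents only; multi-item rules and any causal reading
  of the ORs are out of scope.
- Only slowly-changing categorical data; no vital signs, labs or
  timestamps — re-scoring as items accrue is done by re-invoking
  prediction with the updated itemset.
- The normal-approximation p-value is a large-sample tool: in simulation
  its extreme-tail rejection rate under the null wobbles around nominal
  with count discreteness and becomes anti-conservative when expected
  cells drop to single digits (e.g. P(p < 10⁻⁴) ≈ 2×10⁻⁴ at an expected
  a-cell of ~9). Family-wise control after Bonferroni is therefore
  approximate at small scale — see the null-calibration measurements the
  test suite and acceptance script compute.
- The generator does not model co-occurrence, ICD semantics, or temporal
  structure; minimal-model AUC on synthetic data is not comparable to
  values obtained on real populations.
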