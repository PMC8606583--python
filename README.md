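# orrisk — odds-ratio rule models for in-hospital mortality risk

`orrisk` implements an interpretable associative-classification method for
estimating a patient's in-hospital mortality risk from categorical
electronic-health-record data. It is aimed at researchers in clinical
data science and epidemiology who want a risk model whose every component
is a human-readable epidemiological statement: a rule
*item ⇒ in-hospital mortality* with an odds ratio attached.

## The method

A clinical case is a set of items — (variable type, value) tokens such as
`diagnosis: Acidosis` or `insurance_type: Medicare` — over ten categorical
variable types. Five admission-time, patient-reportable demographic types
(gender, ethnicity, insurance type, language, marital status) form the
**minimal** model class; the **full** class adds diagnoses, prescriptions,
procedures, services and wards.

For every distinct item a 2×2 contingency table against the binary outcome
is counted (a = with item & died, b = with item & survived, c/d without the
item), and the association is measured by the odds ratio

    OR = (a·d) / (b·c),

with OR = 1 meaning no association. Items with any zero cell (OR of 0 or ∞)
are discarded. The remaining candidate rules are filtered by a two-sided
test of H₀: OR = 1 using the normal approximation of the log odds ratio
with the Woolf standard error SE = √(1/a + 1/b + 1/c + 1/d); only rules
with p < p_max survive (optionally Bonferroni-corrected, p < p_max / m over
m executed tests; p_max = 0 keeps exactly the rules whose p-value
underflows to 0).

A new case p is scored by the arithmetic mean OR_p of the odds ratios of
all rules that apply to it, and classified by

    f(p) = high-risk  if OR_p ≥ δ,   low-risk  if OR_p < δ,

where the decision boundary δ is calibrated on training data by maximising
the Youden index J = sensitivity + specificity − 1 on the ROC curve.
The evaluation harness reproduces the full experimental protocol: repeated
random 90/10 train/test splits across a 13-value p_max grid × Bonferroni
on/off (26 configurations), with AUC, rule counts, rules-per-case and
confusion metrics per cell.

Because the clinical dataset the method was developed on requires
credentialed access, the package ships a synthetic population generator
with *planted* odds ratios and MIMIC-like statistical shape (1.79% base
mortality, mutually exclusive demographic categories, many rare clinical
items), so the entire pipeline is testable end to end.

## Worked example

`python examples/worked_example.py` scores the bundled fictional
emergency-department patient against the transcribed published models:

```
minimal model: 5 applying rules, mean OR 0.64 vs boundary 1.015 -> low-risk
full model:    9 applying rules, mean OR 5.328 vs boundary 5.306 -> high-risk

applying rules (full model):
  diagnosis       Acidosis                  OR= 10.96
  diagnosis       Anuria and oliguria       OR= 17.27
  ethnicity       Black/African American    OR=  0.58
  ...
```

The five demographics average to OR 0.64 < 1.015: on admission the patient
looks low-risk. Once acidosis, anuria/oliguria and their treatments are
recorded, the nine-rule mean 5.328 crosses the full model's boundary 5.306
and the case is flagged high-risk — and the rule listing *is* the
explanation shown to the provider.

Other examples: `simulate_mine_predict.py` (generate a synthetic
population, mine and summarise a model), `evaluate_grid.py` (a slice of
the repeated-split protocol), `parameter_recovery.py` (planted-OR
recovery). The same functionality is available as a CLI:

```
orrisk simulate --scale small --seed 5 --out cases.tsv --truth truth.csv
orrisk mine --cases cases.tsv --p-max 0.05 --bonferroni --out model.json
orrisk predict --model model.json --cases cases.tsv --boundary 2.0
orrisk evaluate --cases cases.tsv --grid default --repeats 10 --out results.csv
orrisk report --model model.json
```

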