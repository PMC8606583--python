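"""Score the worked fictional emergency-department patient.

The bundled example models transcribe published rule listings: a 13-rule
minimal model over admission-time demographics (decision boundary 1.015)
and a full model that adds the patient's four clinical rules (boundary
5.306). The patient's risk score is the arithmetic mean of the odds ratios
of the rules that apply to her itemset.
"""

from orrisk import (
    FULL_BOUNDARY,
    MINIMAL_BOUNDARY,
    classify_case,
    fictional_patient,
    load_fixture_rules,
    restrict_to_minimal,
)

patient = fictional_patient()

minimal = load_fixture_rules("minimal")
pred = classify_case(minimal, restrict_to_minimal(patient), MINIMAL_BOUNDARY)
print(f"minimal model: {pred.n_applying_rules} applying rules, "
      f"mean OR {pred.score:.2f} vs boundary {MINIMAL_BOUNDARY} -> {pred.label}")

full = load_fixture_rules("full")
pred = classify_case(full, patient, FULL_BOUNDARY)
print(f"full model:    {pred.n_applying_rules} applying rules, "
      f"mean OR {pred.score:.3f} vs boundary {FULL_BOUNDARY} -> {pred.label}")
print()
print("applying rules (full model):")
for rule in pred.applying_rules:
    print(f"  {rule.antecedent.variable_type.value:15s} "
          f"{rule.antecedent.code:25s} OR={rule.or_value:6.2f}")

# A mean OR below 1 means the demographics alone look protective (low-risk);
# the clinical items (acidosis, anuria/oliguria and their treatments) push
# the mean just above the full model's boundary, flagging high risk.
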