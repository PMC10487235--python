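"""Build a hand-written fuzzy model and predict riboflavin yield.

A single-input Mamdani model for casamino acid with order-preserving rules
(low concentration -> low yield, ...) is evaluated over a few
concentrations. Predictions are in µg/L and always stay inside the
340–440 µg/L output universe; higher casamino acid gives higher predicted
riboflavin because the rules preserve the term order.
"""

import ribofis as rf

rules = [rf.Rule({"casamino": label}, label) for label in ("low", "medium", "high")]
model = rf.build_single_factor_model("casamino", rules)

print("casamino (g/L) -> predicted riboflavin (ug/L)")
for level in (5.0, 8.0, 11.0, 12.5, 16.0, 20.0):
    print(f"  {level:5.1f}        -> {model.predict({'casamino': level}):7.2f}")
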