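"""Percentage of excess risk mediated (PERM) from published odds ratios.

PERM = 100 x (OR_total - OR_adjusted) / (OR_total - 1): the share of the
exposure's excess outcome risk that disappears once the mediator set is
held fixed in a multivariable MR model.
"""

from mrmediate import perm

OR_TOTAL = 1.41  # total effect of the exposure on the outcome
ADJUSTED = {
    "leptin": 1.21,
    "leptin + sleep apnoea": 1.05,
    "leptin + coronary heart disease": 1.08,
    "leptin + systolic blood pressure": 1.11,
}

print(f"total effect OR = {OR_TOTAL}")
for label, or_adj in ADJUSTED.items():
    print(f"adjusted for {label:32s} OR = {or_adj:.2f}  "
          f"PERM = {perm(OR_TOTAL, or_adj):6.2f}%")
print("\nA PERM of 48.78% means the mediator accounts for about half of the "
      "excess risk; values near 100% mean near-complete mediation.")
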