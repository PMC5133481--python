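"""The imputation quality score on a toy variant.

Builds a probability-weighted contingency table for ten individuals and
compares IQS against plain concordance to show why chance-agreement
correction matters for rare variants.
"""

import numpy as np

from pedimpute import build_weighted_table, iqs, kappa

# truth: a rare variant — one het carrier among ten individuals
truth = np.array([0, 0, 0, 0, 0, 0, 0, 0, 0, 1])

# an imputer that always calls hom-ref, confidently
lazy = np.tile([0.97, 0.02, 0.01], (10, 1))
# an imputer that actually finds the carrier
sharp = np.tile([0.98, 0.01, 0.01], (10, 1))
sharp[9] = [0.05, 0.90, 0.05]

for name, post in (("always-ref", lazy), ("carrier-aware", sharp)):
    table = build_weighted_table(truth, post)
    concordance = np.trace(table.cells) / table.total
    print(f"{name:14s} concordance={concordance:.3f}  IQS={iqs(truth, post)}")

print()
print("Weighted table for the carrier-aware imputer:")
print(np.round(build_weighted_table(truth, sharp).cells, 3))
print()
print("The always-ref imputer is 87% concordant but its IQS is None/0-level:")
print("after removing chance agreement it has found nothing; the")
print("carrier-aware imputer keeps a high IQS because it recovered the")
print("single carrier, which is what matters for a rare variant.")
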