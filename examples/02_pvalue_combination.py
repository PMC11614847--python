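"""Fuse per-gene p-values from several tests into one combined p-value.

Shows the six combination methods on two illustrative evidence patterns:
consistent moderate evidence (where sum-based methods like Fisher and
Stouffer shine) and a single strong outlier (where min-p methods like
Tippett react).  The combined p is the probability, under the null of all
four tests, of evidence at least this strong.
"""

import numpy as np

from decombine import COMBINERS

cases = {
    "consistent moderate evidence": [0.04, 0.06, 0.05, 0.07],
    "one strong, three null": [1e-6, 0.60, 0.45, 0.70],
    "all null": [0.50, 0.62, 0.41, 0.55],
}

print(f"{'pattern':32s}" + "".join(f"{n:>17s}" for n in sorted(COMBINERS)))
for label, p in cases.items():
    row = [COMBINERS[name]([p])[0] for name in sorted(COMBINERS)]
    print(f"{label:32s}" + "".join(f"{v:17.3e}" for v in row))

print(
    "\nSum-based methods (fisher, stouffer, lancaster) aggregate the whole "
    "vector,\nso consistent moderate evidence combines to a smaller p than "
    "any input;\nmin-p methods (tippett, wilkinson r=1, bonferroni_holm) "
    "track the best\nsingle test and dominate the outlier pattern."
)
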