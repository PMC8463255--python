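"""Build a clinical-style classification report table.

Given per-category correctly-classified and actual case counts, the
confusion table reproduces the standard three-row report: classification
results, actual results, and half-even-rounded accuracy percentages.
"""

import numpy as np

import rbfseg as rs

table = rs.ConfusionTable(
    class_values=np.array(["head", "abdomen", "knee joint"]),
    correct=[33, 35, 27],
    actual=[35, 36, 29],
)
print(table.to_frame())
print()
print(f"total accuracy: {table.accuracy():.2f}%  "
      f"({table.total_correct}/{table.total_actual} cases)")
print("-> percentages are exact decimal arithmetic, rounded half-even to")
print("   two places, so printed report values are reproduced verbatim.")
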