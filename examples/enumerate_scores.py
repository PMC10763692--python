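"""Exhaustively enumerate all 59,049 possible answer vectors.

Shows the full distribution of Naranjo totals and categories over every
Yes/No/Unknown combination — useful for understanding how the instrument
distributes mass across its four bins.
"""

from collections import Counter

from naranjo import build_naranjo_scale, enumerate_all_vectors

scale = build_naranjo_scale()
total_counts = Counter()
category_counts = Counter()
for _, total, category in enumerate_all_vectors(scale):
    total_counts[total] += 1
    category_counts[category.label] += 1

n = sum(total_counts.values())
print(f"{n} possible answer vectors; totals span "
      f"{min(total_counts)}..{max(total_counts)}")
for label in ("Doubtful", "Possible", "Probable", "Definite"):
    count = category_counts[label]
    print(f"  {label:9s}: {count:6d} vectors ({100 * count / n:5.2f}%)")

# Under the instrument's weights most random answer patterns land in
# Possible/Probable; Definite (score >= 9) requires near-maximal evidence.
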