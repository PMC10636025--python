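"""The hybrid DBF/HP classifier over per-region pattern pairs.

Each limb region (proximal, distal) carries one of four patterns from
the product of DBF presence (SPECT) and HP presence (CT).  The five
classes order disease from 'nothing anywhere' (1) through active
backflow (2), backflow with fibrosis (3), mixed burnt-out regions (4),
to fibrosis without any backflow (5).  Four of the 16 ordered pairs are
not covered by the definitions; the strict policy refuses them, the
nearest policy imputes the closest class.
"""

import itertools

from lymphspect import hybrid_classify
from lymphspect.staging import PATTERNS, PATTERN_LABELS, UnclassifiablePatternError

cases = [
    ("DBF-/HP-", "DBF-/HP-", "no backflow, no fibrosis anywhere"),
    ("DBF-/HP-", "DBF+/HP-", "distal backflow only, no fibrosis"),
    ("DBF+/HP+", "DBF+/HP+", "backflow with fibrosis in both regions"),
    ("DBF-/HP+", "DBF+/HP+", "distal still active, proximal burnt out"),
    ("DBF-/HP+", "DBF-/HP+", "fibrosis only: lymphatics no longer filling"),
]
for prox, dist, meaning in cases:
    cls = hybrid_classify(prox, dist)
    print(f"proximal {prox}, distal {dist} -> Class {cls.value}   ({meaning})")

print("\nfull decision table (proximal rows x distal columns):")
print("          " + "  ".join(f"{PATTERN_LABELS[d]:>8}" for d in PATTERNS))
for p in PATTERNS:
    row = []
    for d in PATTERNS:
        try:
            row.append(str(hybrid_classify(p, d).value))
        except UnclassifiablePatternError:
            row.append("-")
    print(f"{PATTERN_LABELS[p]:>8}  " + "  ".join(f"{c:>8}" for c in row))
print("('-' = not covered; `policy='nearest'` imputes the closest class)")
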