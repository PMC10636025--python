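"""Small reference datasets bundled with the package.

The staging-comparison reference reproduces the published cross-tabulation
of TLS stage calls from a 41-patient secondary extremity-lymphedema cohort
read twice: once on planar scintigraphy alone and once on planar plus
SPECT/CT.  Two patients whose planar reading was corrupted by clothing
contamination (planar P-3 read as combined T-4) are carried with their
contamination flag set; the published table excludes them, leaving 39
evaluable subjects, 6 modified stagings and a 15.4% modification rate.
"""

from __future__ import annotations

import numpy as np

from .core import ContingencyTable
from .staging import STAGE_ORDER, StageCallPair

__all__ = [
    "reference_staging_table",
    "reference_staging_pairs",
]

#: combined-reading rows x planar-reading columns over P-1..T-6 (39 evaluable)
_REFERENCE_LABELS = ("P-1", "P-2", "P-3", "T-4", "T-5", "T-6")
_REFERENCE_COUNTS = np.array(
    [
        #  P-1  P-2  P-3  T-4  T-5  T-6   (planar columns)
        [1,   0,   0,   0,   0,   0],   # combined P-1
        [2,  12,   0,   0,   0,   1],   # combined P-2
        [0,   0,   4,   2,   1,   0],   # combined P-3
        [0,   0,   0,   5,   0,   0],   # combined T-4
        [0,   0,   0,   0,   4,   0],   # combined T-5
        [0,   0,   0,   0,   0,   7],   # combined T-6
    ],
    dtype=int,
)


def reference_staging_table() -> ContingencyTable:
    """The published 6x6 planar vs planar+SPECT/CT stage count table
    (contamination-affected subjects already excluded)."""
    return ContingencyTable(labels=_REFERENCE_LABELS, counts=_REFERENCE_COUNTS.copy())


def reference_staging_pairs(include_contaminated: bool = True) -> list[StageCallPair]:
    """Per-subject stage-call pairs reconstructed from the published table.

    With ``include_contaminated`` the two artifact subjects (planar P-3 ->
    combined T-4, contamination flag set) are appended, restoring the full
    41-patient cohort.
    """
    pairs = []
    k = 0
    for i, combined in enumerate(_REFERENCE_LABELS):
        for j, planar in enumerate(_REFERENCE_LABELS):
            for _ in range(int(_REFERENCE_COUNTS[i, j])):
                pairs.append(StageCallPair(f"ref{k:02d}", planar=planar, combined=combined))
                k += 1
    if include_contaminated:
        for _ in range(2):
            pairs.append(
                StageCallPair(f"ref{k:02d}", planar="P-3", combined="T-4", contamination=True)
            )
            k += 1
    assert all(s in STAGE_ORDER for s in _REFERENCE_LABELS)
    return pairs
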