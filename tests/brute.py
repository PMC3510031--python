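"""Independent brute-force oracles used by the test suite.

These re-derive the aligner's and the NQS filter's contracts from their
definitions with naive, position-by-position code, deliberately sharing no
logic with the package implementation.
"""

from __future__ import annotations

import numpy as np


def brute_score(seq: str, mature: str, flank: str):
    """Naive mismatch classification of a read against one reference.

    Builds the full template (mature followed by flank), compares every read
    position, and classifies each mismatch as 3'-end (inside the read's last
    five bases, or beyond the mature terminus) or internal.  Returns
    (internal, end3, overlap, offset) or None when outside the budgets.
    """
    offset = len(seq) - len(mature)
    if offset > 5:
        return None
    template = mature + flank
    internal = 0
    end3 = 0
    for pos in range(len(seq)):
        if pos >= len(template):
            is_mismatch = True
        else:
            is_mismatch = seq[pos] != template[pos]
        if not is_mismatch:
            continue
        in_terminal_window = pos >= len(seq) - 5
        beyond_terminus = pos >= len(mature)
        if in_terminal_window or beyond_terminus:
            end3 += 1
        else:
            internal += 1
    if internal > 2 or end3 > 5:
        return None
    return internal, end3, min(len(seq), len(mature)), offset


def brute_best(seq: str, catalog):
    """Rank all feasible candidates; returns (name, internal, end3, overlap,
    offset, ambiguous) or None."""
    feasible = []
    for entry in catalog:
        res = brute_score(seq, entry.mature_seq, entry.flank3)
        if res is not None:
            internal, end3, overlap, offset = res
            feasible.append(
                ((internal + end3, internal, -overlap, entry.name),
                 (entry.name, internal, end3, overlap, offset))
            )
    if not feasible:
        return None
    feasible.sort(key=lambda x: x[0])
    key, payload = feasible[0]
    ambiguous = len(feasible) > 1 and feasible[1][0][:3] == key[:3]
    return (*payload, ambiguous)


def brute_nqs(quals, center: int, min_central: int, min_window_mean: float,
              window: int) -> bool:
    """Direct recomputation of the two neighborhood-quality conditions."""
    if quals[center] < min_central:
        return False
    half = window // 2
    neighborhood = [
        quals[i]
        for i in range(center - half, center + half + 1)
        if 0 <= i < len(quals)
    ]
    return sum(neighborhood) / len(neighborhood) >= min_window_mean
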