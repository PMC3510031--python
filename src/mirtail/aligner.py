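"""5'-anchored assignment of trimmed reads to mature miRNAs.

Reads and mature sequences are anchored at their 5' ends (this pipeline only
interrogates 3' variation, and 5' isomiRs are out of scope), so every read
position maps to the same position of a candidate mature sequence.  Read bases
past the mature terminus (the 3' overhang, at most ``MAX_OVERHANG`` nt) are
compared against the genomic flank; overhang bases that differ from the flank
are the non-templated tail signal and are retained verbatim.

Mismatch accounting follows a two-bucket budget: mismatches falling in the
read's terminal ``END3_WINDOW`` bases — plus every overhang base that differs
from the flank — count toward the 3'-end budget (max ``MAX_END3``); all other
mismatches are internal (max ``MAX_INTERNAL``).  ``N`` bases count as
mismatches wherever they are compared.

Candidate ranking: fewest total mismatches, then fewest internal mismatches,
then longest overlap, then lexicographically smallest miRNA name.  When the
name alone breaks the tie the assignment is deterministic but flagged
``ambiguous``; ambiguous reads count in quantification but are excluded from
tail calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .refcat import MiRNARefEntry

__all__ = [
    "TailedAlignment",
    "AlignmentStats",
    "align_read",
    "align_library",
    "MAX_INTERNAL",
    "MAX_END3",
    "MAX_OVERHANG",
    "END3_WINDOW",
]

MAX_INTERNAL = 2  # internal mismatch budget
MAX_END3 = 5      # 3'-end mismatch budget
END3_WINDOW = 5   # terminal bases of the read treated as the 3'-end region
MAX_OVERHANG = 5  # overhangs longer than the 3'-end budget cannot align


@dataclass(slots=True)
class TailedAlignment:
    """A read-to-miRNA assignment with 3'-overhang (tail) bookkeeping.

    ``terminal_read_offset`` locates the read's last base relative to the
    mature 3' terminus: 0 = ends exactly at the terminus, k>0 = k bases
    beyond, k<0 = read stops short of the terminus.  ``overhang_seq`` holds
    the read bases beyond the terminus verbatim (empty when offset <= 0).
    ``read_quals`` keeps the full trimmed-read quality string so neighborhood
    quality filtering can be evaluated at any position downstream.
    """

    read_id: str
    mirna_name: str
    internal_mismatches: int
    end3_mismatches: int
    overlap_len: int
    overhang_seq: str
    overhang_quals: np.ndarray
    terminal_read_base: str
    terminal_read_offset: int
    ambiguous: bool
    read_quals: np.ndarray

    @property
    def read_len(self) -> int:
        return self.overlap_len + max(self.terminal_read_offset, 0)


@dataclass
class AlignmentStats:
    n_input: int = 0
    n_aligned: int = 0
    n_unaligned: int = 0
    n_ambiguous: int = 0

    @property
    def aligned_fraction(self) -> float:
        return self.n_aligned / self.n_input if self.n_input else 0.0


def _score_candidate(
    seq: str, entry: MiRNARefEntry
) -> Optional[tuple[int, int, int, int]]:
    """Score one read sequence against one catalog entry.

    Returns (internal, end3, overlap_len, offset) if the candidate is within
    the mismatch budgets, else None.
    """
    mature = entry.mature_seq
    L, M = len(seq), len(mature)
    offset = L - M
    if offset > MAX_OVERHANG:
        return None
    overlap = min(L, M)
    end3_start = L - END3_WINDOW  # read positions >= this are in the 3'-end region
    internal = 0
    end3 = 0
    for i in range(overlap):
        if seq[i] != mature[i]:
            if i >= end3_start:
                end3 += 1
                if end3 > MAX_END3:
                    return None
            else:
                internal += 1
                if internal > MAX_INTERNAL:
                    return None
    if offset > 0:
        flank = entry.flank3
        for i in range(M, L):
            # overhang position i maps to flank offset i-M+1 (1-based)
            if seq[i] != flank[i - M]:
                end3 += 1
                if end3 > MAX_END3:
                    return None
    return internal, end3, overlap, offset


def _best_candidate(
    seq: str, catalog: list[MiRNARefEntry]
) -> Optional[tuple[MiRNARefEntry, int, int, int, int, bool]]:
    """Best feasible catalog entry for a sequence, with the ambiguity flag."""
    scored = []
    for entry in catalog:
        result = _score_candidate(seq, entry)
        if result is not None:
            internal, end3, overlap, offset = result
            scored.append(
                ((internal + end3, internal, -overlap, entry.name), entry, result)
            )
    if not scored:
        return None
    scored.sort(key=lambda item: item[0])
    key, entry, (internal, end3, overlap, offset) = scored[0]
    ambiguous = len(scored) > 1 and scored[1][0][:3] == key[:3]
    return entry, internal, end3, overlap, offset, ambiguous


def align_read(
    read, catalog: list[MiRNARefEntry]
) -> Optional[TailedAlignment]:
    """Align one trimmed read; returns None when no candidate fits the budget."""
    best = _best_candidate(read.sequence, catalog)
    if best is None:
        return None
    entry, internal, end3, overlap, offset, ambiguous = best
    overhang = read.sequence[len(entry.mature_seq):] if offset > 0 else ""
    return TailedAlignment(
        read_id=read.read_id,
        mirna_name=entry.name,
        internal_mismatches=internal,
        end3_mismatches=end3,
        overlap_len=overlap,
        overhang_seq=overhang,
        overhang_quals=read.qualities[len(entry.mature_seq):] if offset > 0
        else read.qualities[:0],
        terminal_read_base=read.sequence[-1] if read.sequence else "",
        terminal_read_offset=offset,
        ambiguous=ambiguous,
        read_quals=read.qualities,
    )


def align_library(
    reads: Iterable, catalog: list[MiRNARefEntry]
) -> tuple[list[TailedAlignment], AlignmentStats]:
    """Align a stream of trimmed reads, memoizing by read sequence.

    Small-RNA libraries are massively redundant (a handful of isomiR species
    dominate), so candidate scoring is done once per distinct sequence and
    per-read records only attach identity and qualities.
    """
    stats = AlignmentStats()
    cache: dict[str, Optional[tuple]] = {}
    alignments: list[TailedAlignment] = []
    for read in reads:
        stats.n_input += 1
        seq = read.sequence
        if seq in cache:
            best = cache[seq]
        else:
            best = _best_candidate(seq, catalog)
            cache[seq] = best
        if best is None:
            stats.n_unaligned += 1
            continue
        entry, internal, end3, overlap, offset, ambiguous = best
        stats.n_aligned += 1
        if ambiguous:
            stats.n_ambiguous += 1
        mlen = len(entry.mature_seq)
        alignments.append(
            TailedAlignment(
                read_id=read.read_id,
                mirna_name=entry.name,
                internal_mismatches=internal,
                end3_mismatches=end3,
                overlap_len=overlap,
                overhang_seq=seq[mlen:] if offset > 0 else "",
                overhang_quals=read.qualities[mlen:] if offset > 0
                else read.qualities[:0],
                terminal_read_base=seq[-1] if seq else "",
                terminal_read_offset=offset,
                ambiguous=ambiguous,
                read_quals=read.qualities,
            )
        )
    return alignments, stats
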