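"""Calling 3' A/U additions at the +1 position and unambiguous uridylation.

A read reports an addition when it extends past the mature 3' terminus and its
+1 base (the first overhang base) survives neighborhood-quality filtering.  A
+1 nucleotide becomes a *retained variant* for a miRNA only when it reaches
the per-library frequency threshold (default one per 1,000 aligned reads) and
differs from the genomically templated base at offset 1 — a +1 base equal to
the flank is alternative processing, not an enzymatic addition.

Unambiguous uridylation is the stricter complement: a read whose 3'-terminal
base is T while the templated base at that terminal position (mature body for
reads ending at or before the terminus, genomic flank beyond it) is not T.
Such a U cannot be genomically encoded and can only arise from enzymatic
addition.  For mature sequences shared by several catalog entries the non-T
condition must hold against every entry's template.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .aligner import TailedAlignment
from .refcat import MiRNARefEntry, entries_by_mature

__all__ = [
    "NQSParams",
    "ModificationProfile",
    "nqs_pass",
    "call_plus1",
    "detect_unambiguous_uridylation",
    "build_profiles",
    "top_modified",
]


@dataclass(frozen=True)
class NQSParams:
    """Neighborhood quality score thresholds.

    A base call passes when its own Phred score reaches
    ``min_central_quality`` and the mean score over a ``window_length`` window
    centered on it (truncated at read ends) reaches
    ``min_window_mean_quality``.
    """

    min_central_quality: int = 20
    min_window_mean_quality: float = 15.0
    window_length: int = 5

    def __post_init__(self) -> None:
        if self.window_length < 1 or self.window_length % 2 == 0:
            raise ValueError("window_length must be odd and >= 1")
        if self.min_central_quality < 0 or self.min_window_mean_quality < 0:
            raise ValueError("quality thresholds must be non-negative")


def nqs_pass(qualities: Sequence[int], center_index: int, params: NQSParams) -> bool:
    """Neighborhood quality score filter at one position of a read."""
    n = len(qualities)
    if not 0 <= center_index < n:
        raise IndexError(f"center_index {center_index} out of range for {n} scores")
    if qualities[center_index] < params.min_central_quality:
        return False
    half = params.window_length // 2
    lo = max(0, center_index - half)
    hi = min(n, center_index + half + 1)
    window = qualities[lo:hi]
    return float(np.mean(window)) >= params.min_window_mean_quality


@dataclass
class ModificationProfile:
    """Per-(miRNA, library) modification summary.

    ``plus1_counts`` tabulates NQS-passing +1 bases of reads extending beyond
    the mature terminus.  Percentages use the library's total aligned reads
    for the miRNA as denominator and are ``None`` (undefined, not zero) when
    that total is zero, so downstream filters stay honest.
    """

    mirna_name: str
    library_id: str
    total_reads: int
    plus1_counts: dict[str, int] = field(default_factory=dict)
    retained_variants: tuple[str, ...] = ()
    pct_adenylated: float | None = None
    pct_uridylated: float | None = None
    unambiguous_U_count: int = 0
    tail_length_counts: dict[int, int] = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return self.total_reads > 0


def _plus1_center_index(aln: TailedAlignment) -> int:
    # +1 base is the first overhang base; with 5' anchoring its read index is
    # the mature length, which equals overlap_len whenever offset >= 1.
    return aln.overlap_len


def call_plus1(
    alignments: Iterable[TailedAlignment],
    entry: MiRNARefEntry,
    params: NQSParams,
    min_variant_freq: float = 0.001,
    total_reads: int | None = None,
    strict_greater: bool = False,
) -> tuple[dict[str, int], set[str]]:
    """Tabulate NQS-passing +1 bases and decide retained variants.

    ``alignments`` must be unambiguous assignments to ``entry`` from one
    library.  ``total_reads`` is the frequency denominator (defaults to the
    number of alignments given).  A nucleotide is retained when its frequency
    reaches ``min_variant_freq`` (>= by default; ``strict_greater`` switches
    to >) and it differs from the templated flank base at offset 1.

    Returns (plus1_counts, retained_variants).
    """
    alignments = list(alignments)
    if total_reads is None:
        total_reads = len(alignments)
    counts: Counter[str] = Counter()
    for aln in alignments:
        if aln.terminal_read_offset < 1:
            continue
        center = _plus1_center_index(aln)
        if nqs_pass(aln.read_quals, center, params):
            counts[aln.overhang_seq[0]] += 1
    if total_reads == 0:
        return dict(counts), set()
    templated = entry.flank3[0]
    retained = set()
    for base, n in counts.items():
        freq = n / total_reads
        ok = freq > min_variant_freq if strict_greater else freq >= min_variant_freq
        if ok and base != templated:
            retained.add(base)
    return dict(counts), retained


def detect_unambiguous_uridylation(
    alignments: Iterable[TailedAlignment],
    entry: MiRNARefEntry,
    params: NQSParams,
    mature_groups: dict[str, list[MiRNARefEntry]] | None = None,
) -> int:
    """Count NQS-passing reads ending in a U that cannot be templated.

    The read's terminal base must be T while the templated base at the
    terminal position is not T: for ``terminal_read_offset <= 0`` the template
    is the mature sequence at the read's last aligned position; for positive
    offsets it is the genomic flank.  With ``mature_groups`` supplied, the
    non-T condition is required for every catalog entry sharing the mature
    sequence (conservative for multi-locus miRNAs).
    """
    group = (
        mature_groups.get(entry.mature_seq, [entry]) if mature_groups else [entry]
    )
    count = 0
    for aln in alignments:
        if aln.terminal_read_base != "T":
            continue
        read_len = aln.read_len
        if read_len == 0:
            continue
        offset = aln.terminal_read_offset
        if offset > 0:
            if any(len(e.flank3) < offset or e.flank3[offset - 1] == "T" for e in group):
                continue
        else:
            if entry.mature_seq[read_len - 1] == "T":
                continue
        if nqs_pass(aln.read_quals, read_len - 1, params):
            count += 1
    return count


def build_profiles(
    alignments: Iterable[TailedAlignment],
    catalog: list[MiRNARefEntry],
    library_id: str,
    params: NQSParams | None = None,
    min_variant_freq: float = 0.001,
    strict_greater: bool = False,
) -> list[ModificationProfile]:
    """Build one ModificationProfile per catalog miRNA for one library.

    Ambiguous alignments count toward ``total_reads`` (quantification) but are
    excluded from +1 calling, tail-length tabulation and unambiguous-U
    detection.  Catalog miRNAs with no aligned reads still get a profile, with
    undefined (None) percentages.
    """
    params = params or NQSParams()
    groups = entries_by_mature(catalog)
    by_mirna: dict[str, list[TailedAlignment]] = {e.name: [] for e in catalog}
    for aln in alignments:
        by_mirna[aln.mirna_name].append(aln)
    profiles = []
    for entry in catalog:
        alns = by_mirna[entry.name]
        total = len(alns)
        clean = [a for a in alns if not a.ambiguous]
        counts, retained = call_plus1(
            clean, entry, params, min_variant_freq,
            total_reads=total, strict_greater=strict_greater,
        )
        if total > 0:
            pct_a = 100.0 * counts.get("A", 0) / total if "A" in retained else 0.0
            pct_u = 100.0 * counts.get("T", 0) / total if "T" in retained else 0.0
        else:
            pct_a = pct_u = None
        tail_lengths = Counter(
            a.terminal_read_offset for a in clean if 1 <= a.terminal_read_offset <= 5
        )
        profiles.append(
            ModificationProfile(
                mirna_name=entry.name,
                library_id=library_id,
                total_reads=total,
                plus1_counts=counts,
                retained_variants=tuple(sorted(retained)),
                pct_adenylated=pct_a,
                pct_uridylated=pct_u,
                unambiguous_U_count=detect_unambiguous_uridylation(
                    clean, entry, params, groups
                ),
                tail_length_counts=dict(tail_lengths),
            )
        )
    return profiles


def top_modified(
    profiles: Iterable[ModificationProfile],
    n: int = 40,
    by: str = "pct_uridylated",
) -> list[ModificationProfile]:
    """The n most highly modified miRNAs, descending by the given percentage."""
    defined = [p for p in profiles if getattr(p, by) is not None]
    return sorted(defined, key=lambda p: (-getattr(p, by), p.mirna_name))[:n]
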