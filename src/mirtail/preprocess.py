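"""Demultiplexing and 3'-adapter trimming of multiplexed small-RNA reads.

Libraries are multiplexed via barcode-bearing 3' adapters ligated directly to
the RNA insert, so the barcode is read through at the 3' end of every read.
A read is assigned to a sample only when exactly one sample's adapter matches
perfectly; reads with no match, more than one matching adapter, or an insert
length outside the configured gate are discarded with a reason code.

Match rule: the leftmost position at which a prefix of a sample's 3' adapter
(at least ``min_adapter_overlap`` nt, exact match) runs to the end of the read,
or the full adapter occurs anywhere.  "Perfect match" means exact string
equality — no mismatches are tolerated anywhere in the matched region.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SmallRNARead",
    "BarcodeTable",
    "DiscardRecord",
    "read_fastq",
    "write_fastq",
    "demultiplex_and_trim",
    "preprocess_report",
]


@dataclass(slots=True)
class SmallRNARead:
    """A single-end small-RNA read with per-base Phred qualities.

    ``sample_id`` and ``insert_len`` are populated by demultiplexing/trimming.
    """

    read_id: str
    sequence: str
    qualities: np.ndarray  # uint8 Phred scores, one per base
    sample_id: str | None = None
    insert_len: int | None = None

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.qualities)} quality scores "
                f"for {len(self.sequence)} bases"
            )


@dataclass
class BarcodeTable:
    """Per-sample 3' adapter sequences and the insert-length gate.

    ``adapters`` maps sample_id to its full barcode-bearing 3' adapter.  The
    optional conserved 5' adapter is trimmed from the insert prefix only when
    provided; sequencing is assumed to start at the insert by default.
    """

    adapters: dict[str, str]
    adapter5: str | None = None
    min_insert: int = 16
    max_insert: int = 30
    min_adapter_overlap: int = 8

    def __post_init__(self) -> None:
        if not self.adapters:
            raise ValueError("BarcodeTable requires at least one sample adapter")
        seqs = list(self.adapters.values())
        if len(set(seqs)) != len(seqs):
            raise ValueError("adapter sequences must be distinct")
        if self.min_insert < 1:
            raise ValueError("min_insert must be >= 1")
        if self.max_insert < self.min_insert:
            raise ValueError("max_insert must be >= min_insert")


@dataclass(slots=True)
class DiscardRecord:
    read_id: str
    reason: str  # "unrecognizable" | "ambiguous" | "insert_too_short" | "insert_too_long"


def read_fastq(path: str | Path) -> Iterator[SmallRNARead]:
    """Stream a Phred+33 FASTQ file; malformed records raise with context."""
    with open(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                read_id = title.split()[0]
                quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8) - 33
                yield SmallRNARead(read_id=read_id, sequence=seq.upper(), qualities=quals)
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record in {path}: {exc}") from exc


def write_fastq(reads: Iterable[SmallRNARead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            qual = (r.qualities + 33).astype(np.uint8).tobytes().decode("ascii")
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")
            n += 1
    return n


def _match_adapter(seq: str, adapter: str, min_overlap: int) -> int:
    """Leftmost start of a perfect adapter match in ``seq``, or -1.

    A match is either the full adapter anywhere, or a prefix of the adapter
    (>= ``min_overlap`` nt) running exactly to the end of the read (adapter
    run-off at the read end).
    """
    pos = seq.find(adapter)
    if pos >= 0:
        return pos
    # Partial run-off: the longest adapter prefix equal to a read suffix.
    top = min(len(adapter) - 1, len(seq))
    for k in range(top, min_overlap - 1, -1):
        if seq[len(seq) - k:] == adapter[:k]:
            return len(seq) - k
    return -1


def demultiplex_and_trim(
    reads: Iterable[SmallRNARead], table: BarcodeTable
) -> tuple[dict[str, list[SmallRNARead]], list[DiscardRecord]]:
    """Assign reads to samples by 3'-adapter barcode and trim the adapter.

    Returns per-sample lists of trimmed reads plus the discard log.  Every
    input read appears exactly once across the sample outputs and the log.
    """
    by_sample: dict[str, list[SmallRNARead]] = {s: [] for s in table.adapters}
    discards: list[DiscardRecord] = []
    items = list(table.adapters.items())
    for read in reads:
        hits = []
        for sample, adapter in items:
            pos = _match_adapter(read.sequence, adapter, table.min_adapter_overlap)
            if pos >= 0:
                hits.append((sample, pos))
        if not hits:
            discards.append(DiscardRecord(read.read_id, "unrecognizable"))
            continue
        if len(hits) > 1:
            discards.append(DiscardRecord(read.read_id, "ambiguous"))
            continue
        sample, pos = hits[0]
        insert = read.sequence[:pos]
        quals = read.qualities[:pos]
        if table.adapter5 and insert.startswith(table.adapter5):
            cut = len(table.adapter5)
            insert = insert[cut:]
            quals = quals[cut:]
        if len(insert) < table.min_insert:
            discards.append(DiscardRecord(read.read_id, "insert_too_short"))
            continue
        if len(insert) > table.max_insert:
            discards.append(DiscardRecord(read.read_id, "insert_too_long"))
            continue
        by_sample[sample].append(
            SmallRNARead(
                read_id=read.read_id,
                sequence=insert,
                qualities=quals,
                sample_id=sample,
                insert_len=len(insert),
            )
        )
    return by_sample, discards


def preprocess_report(
    discards: list[DiscardRecord], sample_counts: dict[str, int]
) -> pd.DataFrame:
    """Summarize demultiplexing: kept reads per sample, discards per reason.

    Fractions are of total input reads and sum to 1 over the whole table.
    """
    total = sum(sample_counts.values()) + len(discards)
    rows = [
        {"category": f"kept:{sample}", "count": n, "fraction": n / total if total else 0.0}
        for sample, n in sorted(sample_counts.items())
    ]
    reason_counts = Counter(d.reason for d in discards)
    rows += [
        {
            "category": f"discarded:{reason}",
            "count": n,
            "fraction": n / total if total else 0.0,
        }
        for reason, n in sorted(reason_counts.items())
    ]
    return pd.DataFrame(rows, columns=["category", "count", "fraction"])
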