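"""Mature-miRNA reference catalog with genomic 3' flanks.

The catalog couples each mature miRNA sequence (DNA alphabet, T for U) with
the genomic bases immediately downstream of its annotated 3' terminus, on the
same strand.  The flank is what distinguishes a templated extension (the read
simply runs into the genome) from a non-templated tail added enzymatically.

Coordinate convention used throughout the package: flank offsets are 1-based
beyond the mature 3' terminus.  Offset 1 is the first genomic base past the
annotated end ("the +1 position"); offset 0 is the mature terminus itself and
is *not* a flank position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "MiRNARefEntry",
    "CatalogError",
    "load_catalog",
    "templated_base_at",
    "entries_by_mature",
    "write_catalog_tsv",
]

_VALID_BASES = frozenset("ACGT")

MIN_FLANK_LEN = 10


class CatalogError(ValueError):
    """Raised when a reference catalog is malformed."""


@dataclass(frozen=True)
class MiRNARefEntry:
    """One mature miRNA and its downstream genomic flank.

    Attributes
    ----------
    name:
        Unique identifier (opaque string; no registry naming is assumed).
    mature_seq:
        Mature miRNA sequence, sense strand, DNA alphabet (U stored as T).
    flank3:
        Genomic bases immediately 3' of the mature terminus, same strand,
        at least ``MIN_FLANK_LEN`` nt.
    source:
        Free-text provenance tag.
    """

    name: str
    mature_seq: str
    flank3: str
    source: str = field(default="catalog", compare=False)


def _normalize_seq(raw: str, name: str, kind: str) -> str:
    seq = str(raw).strip().upper().replace("U", "T")
    bad = set(seq) - _VALID_BASES
    if bad or not seq:
        raise CatalogError(
            f"{kind} sequence for record {name!r} contains invalid characters "
            f"{sorted(bad) if bad else '(empty)'}; only A/C/G/T/U are allowed"
        )
    return seq


def _read_flanks(path: str | Path) -> dict[str, str]:
    """Read flanks from FASTA or a 2-column (name, flank) TSV."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    flanks: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise CatalogError(
                    f"{path}:{lineno}: expected 2 tab-separated columns (name, flank)"
                )
            flanks[parts[0]] = parts[1]
    return flanks


def load_catalog(mature_fasta: str | Path, flanks: str | Path) -> list[MiRNARefEntry]:
    """Load and validate a catalog from a mature FASTA plus a flank file.

    Every mature record must have a flank record of the same name; duplicate
    names and non-ACGTU characters are rejected with the offending record
    named in the error.
    """
    flank_map = _read_flanks(flanks)
    entries: list[MiRNARefEntry] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(mature_fasta), "fasta"):
        name = rec.id
        if name in seen:
            raise CatalogError(f"duplicate mature record name {name!r}")
        seen.add(name)
        if name not in flank_map:
            raise CatalogError(f"no 3' flank record for mature miRNA {name!r}")
        mature = _normalize_seq(str(rec.seq), name, "mature")
        flank = _normalize_seq(flank_map[name], name, "flank")
        if len(flank) < MIN_FLANK_LEN:
            raise CatalogError(
                f"flank for {name!r} is {len(flank)} nt; need >= {MIN_FLANK_LEN}"
            )
        entries.append(MiRNARefEntry(name=name, mature_seq=mature, flank3=flank))
    if not entries:
        raise CatalogError(f"no records found in {mature_fasta}")
    return entries


def templated_base_at(entry: MiRNARefEntry, offset: int) -> str:
    """Genomic (templated) base at a 1-based offset beyond the mature terminus.

    ``offset=1`` is the first base past the annotated 3' end.  Offset 0 (the
    mature terminus itself) and offsets beyond the stored flank are errors.
    """
    if offset < 1:
        raise ValueError(
            f"offset must be >= 1 (1-based beyond the mature terminus); got {offset}"
        )
    if offset > len(entry.flank3):
        raise ValueError(
            f"offset {offset} beyond available flank ({len(entry.flank3)} nt) "
            f"for {entry.name}"
        )
    return entry.flank3[offset - 1]


def entries_by_mature(catalog: list[MiRNARefEntry]) -> dict[str, list[MiRNARefEntry]]:
    """Group catalog entries by mature sequence.

    Multi-locus miRNAs (identical mature sequence, distinct genomic flanks)
    appear as one group; unambiguous-uridylation calls must hold against every
    flank in the group.
    """
    groups: dict[str, list[MiRNARefEntry]] = {}
    for entry in catalog:
        groups.setdefault(entry.mature_seq, []).append(entry)
    return groups


def write_catalog_tsv(catalog: list[MiRNARefEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tmature_seq\tflank3\tsource\n")
        for e in catalog:
            fh.write(f"{e.name}\t{e.mature_seq}\t{e.flank3}\t{e.source}\n")
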