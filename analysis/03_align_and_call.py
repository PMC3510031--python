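#!/usr/bin/env python
"""Align trimmed reads to the catalog and call 3' tail modifications.

Each trimmed library is aligned 5'-anchored against the mature-miRNA catalog
under the 2-internal/5-terminal mismatch budget; +1-position A/U additions
are called with neighborhood quality filtering and the 1-per-1,000 variant
threshold, and unambiguous (non-genomic) uridylation events are counted.

Writes per-(miRNA, library) modification profiles, per-library read-length
counts, alignment statistics, and the 40 most uridylated miRNAs of the first
wild-type library to results/analysis/.

Run after 02_demultiplex_trim.py.
"""

from pathlib import Path

import pandas as pd

from mirtail import align_library, build_profiles, read_fastq, top_modified
from mirtail.pipeline import profiles_frame
from mirtail.refcat import MiRNARefEntry

TRIM_DIR = Path("scratch/trimmed")
RESULTS = Path("results/analysis")


def load_catalog_tsv(path: Path) -> list[MiRNARefEntry]:
    df = pd.read_csv(path, sep="\t")
    return [
        MiRNARefEntry(r.name_, r.mature_seq, r.flank3, r.source)
        for r in df.rename(columns={"name": "name_"}).itertuples()
    ]


def main() -> None:
    catalog = load_catalog_tsv(RESULTS / "catalog.tsv")
    profiles_by_library = {}
    stats_rows = []
    length_rows = []
    for fastq in sorted(TRIM_DIR.glob("*.fastq")):
        lib = fastq.stem
        reads = list(read_fastq(fastq))
        alignments, astats = align_library(reads, catalog)
        profiles_by_library[lib] = build_profiles(alignments, catalog, lib)
        stats_rows.append(
            {"library": lib, "input": astats.n_input, "aligned": astats.n_aligned,
             "unaligned": astats.n_unaligned, "ambiguous": astats.n_ambiguous,
             "aligned_fraction": astats.aligned_fraction}
        )
        lengths = pd.Series([len(r.sequence) for r in reads]).value_counts()
        for length, count in lengths.sort_index().items():
            length_rows.append({"library": lib, "length": length, "count": count})
        print(f"{lib}: aligned {astats.n_aligned:,}/{astats.n_input:,} "
              f"({100 * astats.aligned_fraction:.2f}%)")

    profiles_frame(profiles_by_library).to_csv(
        RESULTS / "profiles.tsv", sep="\t", index=False
    )
    pd.DataFrame(stats_rows).to_csv(
        RESULTS / "alignment_stats.tsv", sep="\t", index=False
    )
    pd.DataFrame(length_rows).to_csv(
        RESULTS / "length_counts.tsv", sep="\t", index=False
    )
    wt1 = profiles_by_library["wt1"]
    top = top_modified(wt1, n=40)
    pd.DataFrame(
        [{"mirna_name": p.mirna_name, "pct_uridylated": p.pct_uridylated,
          "pct_adenylated": p.pct_adenylated, "total_reads": p.total_reads}
         for p in top]
    ).to_csv(RESULTS / "top40_uridylated_wt1.tsv", sep="\t", index=False)
    print(f"profiles, lengths and top-40 table in {RESULTS}/")


if __name__ == "__main__":
    main()
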