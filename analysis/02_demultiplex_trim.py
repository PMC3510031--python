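#!/usr/bin/env python
"""Demultiplex by 3'-adapter barcode and trim adapters.

Reads each simulated library FASTQ from scratch/sim/, sorts reads by the four
barcode-bearing 3' adapters, trims perfect adapter matches and discards
ambiguous or unrecognizable reads.  Trimmed per-library FASTQs go to
scratch/trimmed/; the per-library trimming summary goes to results/analysis/.

Run after 01_simulate_experiment.py.
"""

from pathlib import Path

import pandas as pd

from mirtail import demultiplex_and_trim, preprocess_report, read_fastq, write_fastq
from mirtail.pipeline import barcode_table_for

from importlib import import_module
import sys

sys.path.insert(0, str(Path(__file__).parent))
CONFIG = import_module("01_simulate_experiment").CONFIG

SIM_DIR = Path("scratch/sim")
TRIM_DIR = Path("scratch/trimmed")
RESULTS = Path("results/analysis")


def main() -> None:
    TRIM_DIR.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(RESULTS / "manifest.tsv", sep="\t")
    table = barcode_table_for(CONFIG)
    summaries = []
    for row in manifest.itertuples():
        for genotype in ("wt", "ko"):
            lib = getattr(row, f"{genotype}_library")
            bc = getattr(row, f"{genotype}_barcode_index")
            by_sample, discards = demultiplex_and_trim(
                read_fastq(SIM_DIR / f"{lib}.fastq"), table
            )
            kept = by_sample[f"bc{bc}"]
            write_fastq(kept, TRIM_DIR / f"{lib}.fastq")
            report = preprocess_report(
                discards, {s: len(v) for s, v in by_sample.items()}
            )
            report.insert(0, "library", lib)
            summaries.append(report)
            print(f"{lib}: kept {len(kept):,} of "
                  f"{len(kept) + len(discards):,} reads "
                  f"({len(discards):,} discarded)")
    pd.concat(summaries).to_csv(RESULTS / "trim_summary.tsv", sep="\t", index=False)
    print(f"trimmed FASTQs in {TRIM_DIR}/, summary in {RESULTS}/trim_summary.tsv")


if __name__ == "__main__":
    main()
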