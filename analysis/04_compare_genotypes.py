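#!/usr/bin/env python
"""Compare wild-type and knockout libraries.

Loads the modification profiles and length counts from 03_align_and_call.py
and runs the comparative statistics: reads-per-million quantification with
the WT/KO log-log Pearson correlation, the read-length histogram with two-way
ANOVA and Bonferroni per-length contrasts, the A and U waterfall fold-change
analyses (geometric-mean KO/WT ratios per miRNA, filtered to miRNAs with
>10,000 summed WT reads and >0.1% WT modification), and the per-genotype
count of consistently uridylated species.

Writes all tables plus summary.json to results/analysis/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from mirtail import (
    genotype_correlation,
    length_histogram_test,
    quantify_rpm,
    species_uridylation_counts,
    waterfall,
)
from mirtail.tailcall import ModificationProfile

RESULTS = Path("results/analysis")


def load_profiles(path: Path) -> dict[str, list[ModificationProfile]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[ModificationProfile]] = {}
    for r in df.itertuples():
        out.setdefault(r.library_id, []).append(
            ModificationProfile(
                mirna_name=r.mirna_name,
                library_id=r.library_id,
                total_reads=int(r.total_reads),
                plus1_counts={b: int(getattr(r, f"plus1_{b}")) for b in "ACGT"},
                retained_variants=tuple(
                    str(r.retained_variants).split(",")
                ) if isinstance(r.retained_variants, str) else (),
                pct_adenylated=None if pd.isna(r.pct_adenylated) else r.pct_adenylated,
                pct_uridylated=None if pd.isna(r.pct_uridylated) else r.pct_uridylated,
                unambiguous_U_count=int(r.unambiguous_U_count),
                tail_length_counts={
                    int(k): v for k, v in json.loads(r.tail_length_counts).items()
                },
            )
        )
    return out


def main() -> None:
    manifest = pd.read_csv(RESULTS / "manifest.tsv", sep="\t")
    profiles = load_profiles(RESULTS / "profiles.tsv")
    lengths_df = pd.read_csv(RESULTS / "length_counts.tsv", sep="\t")
    lengths_by_library = {
        lib: np.repeat(g["length"].to_numpy(), g["count"].to_numpy())
        for lib, g in lengths_df.groupby("library")
    }

    rpm = quantify_rpm(profiles)
    rpm.rename_axis("mirna_name").to_csv(RESULTS / "rpm_matrix.tsv", sep="\t")
    r = genotype_correlation(rpm, manifest)
    print(f"WT vs KO abundance: Pearson r = {r:.3f} on log10(mean RPM + 1) "
          f"over {rpm.shape[0]} miRNAs")

    hist = length_histogram_test(lengths_by_library, manifest)
    hist.fractions.rename_axis("length").to_csv(
        RESULTS / "length_histogram.tsv", sep="\t"
    )
    hist.per_length.to_csv(RESULTS / "length_tests.tsv", sep="\t", index=False)
    sig = hist.per_length[hist.per_length["significant"]]
    print("read lengths with a genotype difference (Bonferroni p < 0.05):",
          sig["length"].tolist() or "none")

    summaries = {}
    for nuc in ("U", "A"):
        wf = waterfall(profiles, manifest, nuc)
        wf.table.to_csv(RESULTS / f"waterfall_{nuc}.tsv", sep="\t", index=False)
        s = wf.summary
        summaries[f"waterfall_{nuc}"] = s
        print(f"{nuc} waterfall: n={s['n_mirnas']} miRNAs, mean log2 FC = "
              f"{s['mean_log2_fc']:.3f} "
              f"[{s['ci_low']:.3f}, {s['ci_high']:.3f}] (p = {s['p']:.2e})")

    species = species_uridylation_counts(profiles, manifest)
    print(f"consistently uridylated species: WT {species['n_wt_species']} vs "
          f"KO {species['n_ko_species']} "
          f"(chi2 = {species['chi2']:.2f}, p = {species['p']:.2e})")

    summaries["genotype_correlation_r"] = r
    summaries["species_counts"] = species
    with open(RESULTS / "summary.json", "w") as fh:
        json.dump(summaries, fh, indent=2, default=float)
    print(f"tables and summary.json in {RESULTS}/")


if __name__ == "__main__":
    main()
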