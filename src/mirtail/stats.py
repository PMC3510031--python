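"""Comparative statistics over paired wild-type/knockout libraries.

The paired design (sex/littermate-matched WT/KO libraries) is described by a
manifest with one row per pair, naming the WT and KO library ids.  All
functions take per-library ``ModificationProfile`` lists keyed by library id,
as produced by :func:`mirtail.tailcall.build_profiles`.

The headline comparison is the waterfall analysis: for each miRNA passing the
wild-type abundance and modification filters, the per-pair ratio of modified
percentages (KO/WT) is combined as a geometric mean across pairs, and the set
of per-miRNA log2 geometric-mean ratios is summarized by its mean, a
t-distribution 95% confidence interval and a one-sample t-test against 0.
Under knockout loss of a uridylyl transferase the U waterfall skews below 1
while the A waterfall stays centered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tailcall import ModificationProfile

__all__ = [
    "FoldChangeTable",
    "LengthHistogram",
    "quantify_rpm",
    "genotype_correlation",
    "length_histogram_test",
    "waterfall",
    "chisq_gof",
    "species_uridylation_counts",
    "run_all",
]


def _genotype_libraries(manifest: pd.DataFrame) -> tuple[list[str], list[str]]:
    return list(manifest["wt_library"]), list(manifest["ko_library"])


def quantify_rpm(
    profiles_by_library: dict[str, list[ModificationProfile]]
) -> pd.DataFrame:
    """miRNA x library reads-per-million matrix.

    RPM = 1e6 * reads / total aligned miRNA reads in the library; each column
    sums to 1e6.  A library with zero aligned reads is an error.
    """
    counts = pd.DataFrame(
        {
            lib: {p.mirna_name: p.total_reads for p in profiles}
            for lib, profiles in profiles_by_library.items()
        }
    ).fillna(0)
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero aligned reads in libraries: {list(zero.index)}")
    return 1e6 * counts / totals


def genotype_correlation(
    rpm: pd.DataFrame,
    manifest: pd.DataFrame,
    epsilon: float = 1.0,
    log_scale: bool = True,
) -> float:
    """Pearson r between mean WT and mean KO abundance per miRNA.

    Restricted to miRNAs detected (>= 1 read) in at least one library of each
    genotype; computed on log10(mean RPM + epsilon) by default since
    abundances span orders of magnitude.
    """
    wt_libs, ko_libs = _genotype_libraries(manifest)
    detected = (rpm[wt_libs].gt(0).any(axis=1)) & (rpm[ko_libs].gt(0).any(axis=1))
    if detected.sum() < 3:
        raise ValueError(
            f"only {int(detected.sum())} miRNAs detected in both genotypes; need >= 3"
        )
    wt = rpm.loc[detected, wt_libs].mean(axis=1)
    ko = rpm.loc[detected, ko_libs].mean(axis=1)
    if log_scale:
        wt, ko = np.log10(wt + epsilon), np.log10(ko + epsilon)
    r, _ = sps.pearsonr(wt, ko)
    return float(r)


@dataclass
class LengthHistogram:
    """Read-length composition per library plus genotype testing."""

    fractions: pd.DataFrame        # length x library, fractions summing to 1
    counts: pd.DataFrame           # length x library raw counts
    anova: pd.DataFrame | None     # two-way ANOVA table (None if skipped)
    per_length: pd.DataFrame | None  # per-length t-test with Bonferroni p


def length_histogram_test(
    lengths_by_library: dict[str, "np.ndarray | list[int]"],
    manifest: pd.DataFrame,
    length_range: tuple[int, int] = (15, 30),
    alpha: float = 0.05,
) -> LengthHistogram:
    """Histogram trimmed-read lengths per library and test genotype effects.

    Per-library counts over ``length_range`` are converted to fractions
    (summing to 1 per library) and analyzed by two-way fixed-effects ANOVA
    with genotype and length as factors; per-length genotype contrasts are
    two-sample t-tests Bonferroni-corrected across the number of lengths
    tested.  With fewer than 2 libraries in a genotype the tests are skipped
    with a warning and only the descriptive histogram is returned.
    """
    lmin, lmax = length_range
    index = list(range(lmin, lmax + 1))
    counts = pd.DataFrame(index=index)
    for lib, lengths in lengths_by_library.items():
        arr = np.asarray(lengths, dtype=int)
        arr = arr[(arr >= lmin) & (arr <= lmax)]
        counts[lib] = pd.Series(arr).value_counts().reindex(index, fill_value=0)
    fractions = counts / counts.sum(axis=0)

    wt_libs, ko_libs = _genotype_libraries(manifest)
    if len(wt_libs) < 2 or len(ko_libs) < 2:
        warnings.warn(
            "need >= 2 libraries per genotype for the two-way ANOVA; "
            "emitting descriptive histogram only"
        )
        return LengthHistogram(fractions, counts, None, None)

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    long = fractions.reset_index(names="length").melt(
        id_vars="length", var_name="library", value_name="frac"
    )
    long["genotype"] = np.where(long["library"].isin(wt_libs), "WT", "KO")
    model = smf.ols("frac ~ C(genotype) * C(length)", data=long).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    rows = []
    n_tests = len(index)
    for length in index:
        wt_frac = fractions.loc[length, wt_libs].to_numpy(dtype=float)
        ko_frac = fractions.loc[length, ko_libs].to_numpy(dtype=float)
        if np.allclose(wt_frac, wt_frac[0]) and np.allclose(ko_frac, ko_frac[0]) \
                and np.isclose(wt_frac[0], ko_frac[0]):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(wt_frac, ko_frac)
            if np.isnan(p):
                t, p = 0.0, 1.0
        rows.append(
            {
                "length": length,
                "wt_mean_frac": wt_frac.mean(),
                "ko_mean_frac": ko_frac.mean(),
                "t": float(t),
                "p_raw": float(p),
                "p_bonferroni": float(min(1.0, p * n_tests)),
            }
        )
    per_length = pd.DataFrame(rows)
    per_length["significant"] = per_length["p_bonferroni"] < alpha
    return LengthHistogram(fractions, counts, anova, per_length)


@dataclass
class FoldChangeTable:
    """Per-miRNA paired KO/WT modification ratios plus the summary test."""

    nucleotide: str                # "A" or "U"
    table: pd.DataFrame            # per-miRNA rows incl. exclusion reasons
    summary: dict = field(default_factory=dict)

    @property
    def included(self) -> pd.DataFrame:
        return self.table[self.table["included"]]


def _pct(profile: ModificationProfile, nucleotide: str) -> float | None:
    return profile.pct_uridylated if nucleotide == "U" else profile.pct_adenylated


def waterfall(
    profiles_by_library: dict[str, list[ModificationProfile]],
    manifest: pd.DataFrame,
    nucleotide: str,
    min_reads: int = 10_000,
    min_pct: float = 0.1,
) -> FoldChangeTable:
    """Paired KO/WT fold-change analysis of +1 modification percentages.

    Inclusion requires, in the wild-type libraries pooled, more than
    ``min_reads`` summed reads and a pooled modified percentage above
    ``min_pct``.  Per-pair ratios are pct_KO / pct_WT; when a percentage is 0
    a pseudocount of half the minimum detectable percent in that library
    (0.5 / total_reads * 100) is added to both numerator and denominator of
    that pair.  The per-miRNA statistic is the geometric mean of the per-pair
    ratios; the summary is over log2 geometric-mean ratios (mean, 95% t CI,
    one-sample t-test vs 0).
    """
    if nucleotide not in ("A", "U"):
        raise ValueError("nucleotide must be 'A' or 'U'")
    if len(manifest) < 2:
        raise ValueError("need >= 2 WT/KO pairs")
    wt_libs, ko_libs = _genotype_libraries(manifest)
    by_lib = {
        lib: {p.mirna_name: p for p in profiles}
        for lib, profiles in profiles_by_library.items()
    }
    mirnas = sorted({p.mirna_name for ps in profiles_by_library.values() for p in ps})

    rows = []
    for mirna in mirnas:
        wt_profiles = [by_lib[lib][mirna] for lib in wt_libs if mirna in by_lib[lib]]
        wt_total = sum(p.total_reads for p in wt_profiles)
        pooled_num = sum(
            (_pct(p, nucleotide) or 0.0) / 100.0 * p.total_reads for p in wt_profiles
        )
        pooled_pct = 100.0 * pooled_num / wt_total if wt_total else 0.0
        row: dict = {
            "mirna_name": mirna,
            "wt_total_reads": wt_total,
            "wt_pooled_pct": pooled_pct,
            "included": False,
            "exclusion_reason": "",
            "geomean_ratio": np.nan,
        }
        if wt_total <= min_reads:
            row["exclusion_reason"] = "min_reads"
            rows.append(row)
            continue
        if pooled_pct <= min_pct:
            row["exclusion_reason"] = "min_pct"
            rows.append(row)
            continue
        log_ratios = []
        for k, (wt_lib, ko_lib) in enumerate(zip(wt_libs, ko_libs), start=1):
            pw_prof = by_lib[wt_lib].get(mirna)
            pk_prof = by_lib[ko_lib].get(mirna)
            if (
                pw_prof is None or pk_prof is None
                or not pw_prof.defined or not pk_prof.defined
            ):
                row[f"ratio_pair{k}"] = np.nan
                continue
            pw = _pct(pw_prof, nucleotide) or 0.0
            pk = _pct(pk_prof, nucleotide) or 0.0
            if pw == 0.0 or pk == 0.0:
                pw += 0.5 / pw_prof.total_reads * 100.0
                pk += 0.5 / pk_prof.total_reads * 100.0
            ratio = pk / pw
            row[f"ratio_pair{k}"] = ratio
            log_ratios.append(np.log(ratio))
        if not log_ratios:
            row["exclusion_reason"] = "undefined"
            rows.append(row)
            continue
        row["included"] = True
        row["geomean_ratio"] = float(np.exp(np.mean(log_ratios)))
        rows.append(row)

    table = pd.DataFrame(rows).sort_values(
        "geomean_ratio", ascending=True, na_position="last"
    ).reset_index(drop=True)
    included = table[table["included"]]
    n = len(included)
    summary: dict = {"nucleotide": nucleotide, "n_mirnas": n}
    if n == 0:
        warnings.warn(f"no miRNA passes the {nucleotide} waterfall filters")
        summary.update(
            mean_log2_fc=np.nan, ci_low=np.nan, ci_high=np.nan, t=np.nan, p=np.nan
        )
    else:
        l2 = np.log2(included["geomean_ratio"].to_numpy(dtype=float))
        mean = float(l2.mean())
        if n > 1:
            sd = l2.std(ddof=1)
            sem = sd / np.sqrt(n)
            half = float(sps.t.ppf(0.975, n - 1) * sem)
            if sd == 0.0:  # degenerate: all log-ratios identical
                t_stat = 0.0 if mean == 0.0 else float(np.sign(mean) * np.inf)
                p = 1.0 if mean == 0.0 else 0.0
            else:
                t_stat, p = sps.ttest_1samp(l2, 0.0)
                t_stat, p = float(t_stat), float(p)
        else:
            half, t_stat, p = np.nan, np.nan, np.nan
        summary.update(
            mean_log2_fc=mean, ci_low=mean - half, ci_high=mean + half,
            t=t_stat, p=p,
        )
    return FoldChangeTable(nucleotide=nucleotide, table=table, summary=summary)


def chisq_gof(
    observed: "list[int] | np.ndarray", expected_props: "list[float] | np.ndarray"
) -> tuple[float, int, float]:
    """Chi-squared goodness of fit of observed counts to expected proportions.

    Returns (chi2, df, p) with df = number of categories - 1.
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_props, dtype=float)
    if obs.shape != props.shape:
        raise ValueError(
            f"observed ({obs.shape}) and expected_props ({props.shape}) differ in length"
        )
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("expected_props must sum to 1")
    expected = props * obs.sum()
    if np.any(expected <= 0):
        raise ValueError("all expected counts must be > 0")
    chi2, p = sps.chisquare(obs, f_exp=expected)
    return float(chi2), len(obs) - 1, float(p)


def species_uridylation_counts(
    profiles_by_library: dict[str, list[ModificationProfile]],
    manifest: pd.DataFrame,
    min_events: int = 1,
) -> dict:
    """Count species with unambiguous uridylation in every library, per genotype.

    The universe is the set of miRNAs observed (>= 1 read) in every library of
    both genotypes.  A species counts for a genotype when its
    ``unambiguous_U_count`` reaches ``min_events`` in every library of that
    genotype.  The genotype counts are compared by a chi-squared goodness of
    fit against equal proportions.
    """
    wt_libs, ko_libs = _genotype_libraries(manifest)
    all_libs = wt_libs + ko_libs
    by_lib = {
        lib: {p.mirna_name: p for p in profiles}
        for lib, profiles in profiles_by_library.items()
    }
    universe = [
        m
        for m in sorted({p.mirna_name for ps in profiles_by_library.values() for p in ps})
        if all(m in by_lib[lib] and by_lib[lib][m].total_reads >= 1 for lib in all_libs)
    ]
    if not universe:
        raise ValueError("no miRNA observed in every library of both genotypes")

    def hits(libs: list[str]) -> int:
        return sum(
            1
            for m in universe
            if all(by_lib[lib][m].unambiguous_U_count >= min_events for lib in libs)
        )

    n_wt, n_ko = hits(wt_libs), hits(ko_libs)
    if n_wt + n_ko > 0:
        chi2, df, p = chisq_gof([n_wt, n_ko], [0.5, 0.5])
    else:
        chi2, df, p = 0.0, 1, 1.0
    return {
        "universe_size": len(universe),
        "n_wt_species": n_wt,
        "n_ko_species": n_ko,
        "chi2": chi2,
        "df": df,
        "p": p,
    }


def run_all(config, outdir, **kwargs):
    """End-to-end pipeline driver; see :func:`mirtail.pipeline.run_all`."""
    from .pipeline import run_all as _run_all

    return _run_all(config, outdir, **kwargs)
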