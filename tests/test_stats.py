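import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mirtail import chisq_gof, genotype_correlation, length_histogram_test, quantify_rpm, species_uridylation_counts, waterfall
from mirtail.tailcall import ModificationProfile


def manifest(n_pairs=3):
    return pd.DataFrame(
        {
            "pair_id": [f"pair{i+1}" for i in range(n_pairs)],
            "wt_library": [f"wt{i+1}" for i in range(n_pairs)],
            "ko_library": [f"ko{i+1}" for i in range(n_pairs)],
        }
    )


def profile(mirna, total, pct_u=None, pct_a=None, unambig=0, lib="lib"):
    return ModificationProfile(
        mirna_name=mirna, library_id=lib, total_reads=total,
        pct_uridylated=pct_u, pct_adenylated=pct_a, unambiguous_U_count=unambig,
    )


def profiles_dict(spec):
    """spec: {lib: [(mirna, total, pct_u, pct_a, unambig), ...]}"""
    return {
        lib: [profile(m, t, pu, pa, ua, lib=lib) for (m, t, pu, pa, ua) in rows]
        for lib, rows in spec.items()
    }


class TestRPM:
    def test_rpm_arithmetic(self):
        pbl = {
            "wt1": [profile("a", 2_000, 0, 0), profile("b", 1_998_000, 0, 0)]
        }
        rpm = quantify_rpm(pbl)
        assert rpm.loc["a", "wt1"] == pytest.approx(1_000.0)

    def test_single_mirna_library_is_one_million(self):
        rpm = quantify_rpm({"wt1": [profile("a", 123, 0, 0)]})
        assert rpm.loc["a", "wt1"] == pytest.approx(1e6)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        pbl = {
            lib: [profile(f"m{i}", int(n), 0, 0)
                  for i, n in enumerate(rng.integers(1, 1000, 40))]
            for lib in ("wt1", "ko1")
        }
        rpm = quantify_rpm(pbl)
        assert np.allclose(rpm.sum(axis=0), 1e6)

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError, match="zero aligned"):
            quantify_rpm({"wt1": [profile("a", 0, None, None)]})


class TestGenotypeCorrelation:
    def test_identical_matrices_give_r_one(self):
        counts = {"a": 100, "b": 1000, "c": 50, "d": 7}
        pbl = {
            lib: [profile(m, n, 0, 0) for m, n in counts.items()]
            for lib in ("wt1", "ko1")
        }
        rpm = quantify_rpm(pbl)
        r = genotype_correlation(rpm, manifest(1))
        assert r == pytest.approx(1.0)

    def test_antiranked_linear_toy_vectors(self):
        pbl = {
            "wt1": [profile(m, n, 0, 0) for m, n in zip("abc", (1, 2, 3))],
            "ko1": [profile(m, n, 0, 0) for m, n in zip("abc", (3, 2, 1))],
        }
        rpm = quantify_rpm(pbl)
        # raw counts (1,2,3) vs (3,2,1) scale to RPM proportionally
        r = genotype_correlation(rpm, manifest(1), log_scale=False)
        assert r == pytest.approx(-1.0)

    def test_fewer_than_three_shared_mirnas_fails(self):
        pbl = {
            "wt1": [profile("a", 10, 0, 0), profile("b", 0, None, None)],
            "ko1": [profile("a", 10, 0, 0), profile("b", 5, 0, 0)],
        }
        rpm = quantify_rpm(pbl)
        with pytest.raises(ValueError, match="need >= 3"):
            genotype_correlation(rpm, manifest(1))


class TestLengthHistogram:
    def test_identical_distributions_nothing_significant(self):
        lengths = np.repeat([20, 21, 22, 23], [10, 40, 30, 20])
        data = {lib: lengths for lib in
                ("wt1", "wt2", "wt3", "ko1", "ko2", "ko3")}
        res = length_histogram_test(data, manifest())
        assert not res.per_length["significant"].any()
        assert np.allclose(res.fractions.sum(axis=0), 1.0)

    def test_bonferroni_matches_direct_recomputation(self):
        rng = np.random.default_rng(1)
        data = {
            lib: rng.choice(np.arange(18, 26), size=2000,
                            p=np.full(8, 1 / 8)).tolist()
            for lib in ("wt1", "wt2", "wt3", "ko1", "ko2", "ko3")
        }
        res = length_histogram_test(data, manifest())
        n = len(res.per_length)
        for row in res.per_length.itertuples():
            assert row.p_bonferroni == pytest.approx(min(1.0, row.p_raw * n))

    def test_single_library_genotype_skips_tests_with_warning(self):
        data = {"wt1": [20, 21, 22], "ko1": [20, 21, 22]}
        with pytest.warns(UserWarning, match="2 libraries"):
            res = length_histogram_test(data, manifest(1))
        assert res.anova is None and res.per_length is None
        assert res.fractions.shape[1] == 2

    def test_planted_23nt_reduction_is_minimal_adjusted_p(self):
        """A 30% knockout-specific depletion of 23-nt reads is detected at
        that length with the smallest Bonferroni-adjusted p."""
        rng = np.random.default_rng(7)
        base = np.array([2, 5, 10, 20, 25, 15, 13, 6, 3, 1], dtype=float)
        base /= base.sum()  # lengths 17..26, 23-nt fraction 13/100
        i23 = 23 - 17
        ko = base.copy()
        ko[i23] *= 0.7
        ko /= ko.sum()
        lengths = np.arange(17, 27)
        data = {}
        for i in range(3):
            data[f"wt{i+1}"] = np.repeat(
                lengths, rng.multinomial(100_000, base))
            data[f"ko{i+1}"] = np.repeat(
                lengths, rng.multinomial(100_000, ko))
        res = length_histogram_test(data, manifest())
        best = res.per_length.loc[res.per_length["p_bonferroni"].idxmin()]
        assert best["length"] == 23
        assert best["p_bonferroni"] < 0.05
        assert best["ko_mean_frac"] < best["wt_mean_frac"]
        # the genotype x length interaction carries the planted effect
        assert res.anova.loc["C(genotype):C(length)", "PR(>F)"] < 0.05


class TestWaterfall:
    def null_profiles(self, pct=2.0, total=20_000):
        spec = {}
        for lib in ("wt1", "wt2", "wt3", "ko1", "ko2", "ko3"):
            spec[lib] = [(f"m{i}", total, pct, pct, 1) for i in range(5)]
        return profiles_dict(spec)

    def test_null_gives_unit_ratios_and_zero_t(self):
        res = waterfall(self.null_profiles(), manifest(), "U")
        assert res.included["geomean_ratio"].tolist() == pytest.approx([1.0] * 5)
        assert res.summary["mean_log2_fc"] == pytest.approx(0.0)
        assert res.summary["t"] == pytest.approx(0.0)

    def test_geometric_mean_identity(self):
        pbl = profiles_dict({
            "wt1": [("m", 20_000, 1.0, 1.0, 0)],
            "wt2": [("m", 20_000, 1.0, 1.0, 0)],
            "wt3": [("m", 20_000, 1.0, 1.0, 0)],
            "ko1": [("m", 20_000, 2.0, 1.0, 0)],
            "ko2": [("m", 20_000, 0.5, 1.0, 0)],
            "ko3": [("m", 20_000, 1.0, 1.0, 0)],
        })
        res = waterfall(pbl, manifest(), "U")
        assert res.included["geomean_ratio"].item() == pytest.approx(1.0)

    def test_min_reads_filter_excludes_and_names_reason(self):
        pbl = profiles_dict({
            lib: [("m", 3_000, 2.0, 2.0, 0)]
            for lib in ("wt1", "wt2", "wt3", "ko1", "ko2", "ko3")
        })  # 9,000 summed WT reads
        res = waterfall(pbl, manifest(), "U")
        row = res.table.iloc[0]
        assert not row["included"]
        assert row["exclusion_reason"] == "min_reads"

    def test_min_pct_filter(self):
        pbl = profiles_dict({
            lib: [("m", 20_000, 0.05, 0.05, 0)]
            for lib in ("wt1", "wt2", "wt3", "ko1", "ko2", "ko3")
        })
        res = waterfall(pbl, manifest(), "U")
        assert res.table.iloc[0]["exclusion_reason"] == "min_pct"

    def test_zero_percent_uses_pseudocount(self):
        pbl = profiles_dict({
            "wt1": [("m", 20_000, 1.0, 0, 0)],
            "wt2": [("m", 20_000, 1.0, 0, 0)],
            "wt3": [("m", 20_000, 1.0, 0, 0)],
            "ko1": [("m", 20_000, 0.0, 0, 0)],
            "ko2": [("m", 20_000, 0.0, 0, 0)],
            "ko3": [("m", 20_000, 0.0, 0, 0)],
        })
        res = waterfall(pbl, manifest(), "U")
        row = res.included.iloc[0]
        pseudo = 0.5 / 20_000 * 100
        assert row["geomean_ratio"] == pytest.approx(pseudo / (1.0 + pseudo))

    def test_no_survivors_warns_and_is_empty(self):
        pbl = profiles_dict({
            lib: [("m", 100, 0.01, 0.01, 0)]
            for lib in ("wt1", "wt2", "wt3", "ko1", "ko2", "ko3")
        })
        with pytest.warns(UserWarning, match="no miRNA passes"):
            res = waterfall(pbl, manifest(), "U")
        assert len(res.included) == 0
        assert np.isnan(res.summary["mean_log2_fc"])

    def test_requires_two_pairs(self):
        with pytest.raises(ValueError, match="pairs"):
            waterfall(self.null_profiles(), manifest(1), "U")


class TestChisqGof:
    def test_printed_species_counts(self):
        chi2, df, p = chisq_gof([179, 118], [0.5, 0.5])
        assert chi2 == pytest.approx(12.5286, abs=1e-3)
        assert df == 1
        assert p == pytest.approx(4.0e-4, rel=0.05)

    def test_perfect_fit(self):
        chi2, df, p = chisq_gof([150, 150], [0.5, 0.5])
        assert (chi2, df, p) == (0.0, 1, 1.0)

    def test_quarter_proportions_closed_form(self):
        chi2, df, p = chisq_gof([20, 80], [0.25, 0.75])
        assert chi2 == pytest.approx(4 / 3)
        assert p == pytest.approx(0.248, abs=0.001)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            chisq_gof([1, 2, 3], [0.5, 0.5])

    def test_agrees_with_exact_binomial_midp_oracle(self):
        """For two categories the chi-squared p tracks the exact doubled-tail
        mid-p binomial probability (within the normal-approximation error)."""
        worst = 0.0
        for n in range(20, 51, 6):
            for k in range(3, n - 2):
                for p0 in (0.5, 0.25):
                    if n * p0 < 5 or n * (1 - p0) < 5:
                        continue
                    _, _, p = chisq_gof([k, n - k], [p0, 1 - p0])
                    lo = sps.binom.cdf(k, n, p0)
                    hi = sps.binom.sf(k - 1, n, p0)
                    midp = min(1.0, 2 * min(lo, hi) - sps.binom.pmf(k, n, p0))
                    worst = max(worst, abs(p - midp))
        assert worst < 0.05


class TestSpeciesCounts:
    def base_spec(self, ua_ko=1):
        spec = {}
        for lib in ("wt1", "wt2", "wt3"):
            spec[lib] = [("a", 100, 0, 0, 2), ("b", 100, 0, 0, 1), ("c", 100, 0, 0, 0)]
        for lib in ("ko1", "ko2", "ko3"):
            spec[lib] = [("a", 100, 0, 0, ua_ko), ("b", 100, 0, 0, 0), ("c", 100, 0, 0, 0)]
        return spec

    def test_counts_require_events_in_every_library(self):
        res = species_uridylation_counts(profiles_dict(self.base_spec()), manifest())
        assert res["n_wt_species"] == 2  # a and b in all WT libraries
        assert res["n_ko_species"] == 1  # only a

    def test_mirna_absent_from_one_library_leaves_universe(self):
        spec = self.base_spec()
        spec["ko2"] = [("a", 100, 0, 0, 1), ("b", 0, None, None, 0), ("c", 100, 0, 0, 0)]
        res = species_uridylation_counts(profiles_dict(spec), manifest())
        assert res["universe_size"] == 2  # b dropped
        assert res["n_wt_species"] == 1

    def test_empty_universe_is_an_error(self):
        spec = {lib: [("a", 0, None, None, 0)]
                for lib in ("wt1", "wt2", "wt3", "ko1", "ko2", "ko3")}
        with pytest.raises(ValueError, match="no miRNA"):
            species_uridylation_counts(profiles_dict(spec), manifest())

    def test_chi_squared_attached_to_counts(self):
        res = species_uridylation_counts(profiles_dict(self.base_spec()), manifest())
        chi2, df, p = chisq_gof(
            [res["n_wt_species"], res["n_ko_species"]], [0.5, 0.5]
        )
        assert res["chi2"] == pytest.approx(chi2)
        assert res["p"] == pytest.approx(p)
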