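# Methods

This note documents the models, parameter choices and numerical conventions
behind `mirtail`, and what the simulation-based tests do and do not
demonstrate about real sequencing data.

## The measurement model

A mature miRNA is a 20–24 nt RNA whose annotated 3′ terminus is the reference
point. Non-canonical poly(A) polymerases/TUTases append non-templated A or U
residues to that terminus, so in a sequencing library a tailed molecule reads
as `mature + tail + 3′ adapter`. Two confounders must be separated from true
enzymatic addition:

* **Templated extension.** If the genomic base immediately downstream of the
  terminus equals the observed extra base, the read could be an alternative
  processing product rather than an addition. The catalog therefore stores,
  per miRNA, the downstream genomic flank, and a +1 variant is only *retained*
  when it differs from the templated base. The complementary, stricter
  statistic — *unambiguous uridylation* — counts terminal U's whose templated
  base is not T; for mature sequences shared by several loci the non-T
  condition must hold for every locus's flank (conservative by design).
* **Sequencing error.** A +1 base is only counted when it passes the
  neighborhood quality score (NQS) filter, and a +1 nucleotide is only
  retained when it reaches a per-library frequency threshold.

Flank offsets are 1-based beyond the mature terminus everywhere: offset 1 is
the +1 position; offset 0 is the terminus itself and is deliberately an
error, to keep the convention testable.

## Alignment

Reads and mature sequences are anchored at the 5′ end; the pipeline
interrogates only 3′ variation, and anchoring is what makes "internal" versus
"3′-end" mismatches well defined. The 3′-end region is the read's terminal
5 nt plus every base beyond the mature terminus (a 3′-end budget of 5
suggests a 5-nt window; the window size is a package constant,
`aligner.END3_WINDOW`). Budgets: ≤ 2 internal and ≤ 5 3′-end mismatches;
overhangs longer than 5 nt cannot align. `N` compares unequal to everything.

Candidates are ranked by (total mismatches, internal mismatches, −overlap,
name); the name makes the order total, so assignment is deterministic, but a
read whose tie is broken only by name is flagged *ambiguous*: it still counts
in quantification (the molecule exists) but is excluded from tail calling
(family cross-talk would otherwise inflate modification calls). Reads
shorter than the mature sequence (negative terminal offset) quantify and
enter length histograms but cannot produce +1 calls.

The library-level aligner memoizes candidate scoring by read sequence —
small-RNA libraries are massively redundant — and is verified against a
brute-force enumerator, exhaustively over all 4⁸ length-8 reads on a toy
catalog and on randomized mixed-length reads.

## NQS filtering

`nqs_pass` requires a central Phred ≥ 20 and a mean ≥ 15 over a 5-base window
centered on the call, truncated at read ends. The historical neighborhood
quality score used larger neighborhoods; the window here is configurable
(`NQSParams.window_length`, odd). The filter is applied at the variant
position only (the +1 base, or the terminal base for unambiguous-U calls),
not to every aligned base.

## Variant threshold

The retention threshold is ≥ 1 per 1,000 aligned reads for that miRNA in that
library (`min_variant_freq = 0.001`, comparator inclusive; a strict `>` is
available via `strict_greater`). Percent modified uses the miRNA's total
aligned reads — including ambiguous ones — as denominator, keeping the
quantification and modification denominators identical. MiRNAs with zero
reads get *undefined* (`None`) percentages rather than 0, so downstream
filters cannot silently treat absence as evidence.

## Comparative statistics

* **RPM**: 10⁶ × reads / library total; columns sum to 10⁶ by construction.
* **Genotype correlation**: Pearson on log₁₀(mean RPM + 1) over miRNAs
  detected in at least one library of each genotype; abundances span orders
  of magnitude, so the log scale is the default (linear available).
* **Length histogram**: per-library fractions over 15–30 nt; two-way
  fixed-effects ANOVA (genotype × length) on the fractions plus per-length
  two-sample t-tests, Bonferroni-corrected by the number of lengths tested.
  Because fractions sum to 1 per library, the genotype main effect is
  structurally null and the interaction term carries any signal.
* **Waterfall**: per miRNA, per pair, ratio = %modified(KO)/%modified(WT);
  pairs are manifest-defined (matched animals). Inclusion filters are applied
  to the WT libraries pooled: summed reads > 10,000 and pooled percent
  > 0.1 %. When a percent is exactly 0, half the minimum detectable percent
  in that library (0.5/total·100) is added to both members of that pair — a
  pseudocount keeps the geometric mean defined without biasing non-zero
  pairs. The per-miRNA statistic is the geometric mean of pair ratios; the
  summary tests the mean of log₂ ratios against 0 (one-sample t, 95 % CI on
  the t distribution with n−1 df). Degenerate all-equal ratios give t = 0,
  p = 1 rather than NaN.
* **Species counts**: over the universe of miRNAs observed (≥ 1 read) in
  every library of both genotypes, a species counts for a genotype when it
  shows ≥ 1 NQS-passing unambiguous-U read in *every* library of that
  genotype (`min_events` configurable). The two counts are compared by χ²
  goodness of fit against equal proportions; a 2×2 contingency alternative
  can be built from the returned counts and universe size.
* **χ² goodness of fit** is Σ(obs−exp)²/exp with df = k−1. For two
  categories it is validated against an exact doubled-tail mid-p binomial
  oracle to within 0.05; agreement tighter than that is not attainable in
  the worst case because the χ² statistic is itself a normal approximation
  (worst-case deviation ≈ 0.035 even with all expected counts ≥ 5).

## The simulator

`simlib` emulates the statistical structure the analysis assumes, not the
biochemistry of library construction:

* **Design**: 3 WT/KO pairs by default, four 6-nt barcodes prepended to a
  common adapter core, equal depth per library (depth balance across barcodes
  is an assumption; it is configurable).
* **Expression**: log-normal weights (σ = 1 by default), normalized per
  library — a realistic heavy-tailed miRNA abundance spectrum.
* **Tailing**: per-miRNA U- and A-tailing probabilities drawn uniformly from
  configured ranges (defaults 1–10 % U, 1–6 % A, the low-percent regime in
  which terminal modification of abundant miRNAs is typically observed);
  tails are homopolymers of length 1–4 with geometric decay (ratio 0.45), so
  mono-uridylation dominates. The knockout multiplies the U probability by
  `ko_u_factor` (default 0.3) and leaves A alone — a multiplicative loss on
  U only, matching the expected signature of a uridylyl-transferase
  knockout. There is no simulated quantity effect.
* **Templated confounders**: 25 % of flanks begin with T (≈ the genomic base
  frequency), creating miRNAs whose +1 U can never be called — these exercise
  the templated-exclusion logic and are removed by the min-percent filter in
  the U waterfall.
* **Errors and qualities**: substitutions only (no indels — the mismatch
  budget concerns substitutions, and indel-free truth bookkeeping stays
  exact) at a per-base rate (default 0.1 %). Error positions receive Phred
  scores from a low-quality Gaussian (mean 12, sd 4) and correct bases from
  the main model (mean 34, sd 3), both clipped to [2, 40]; coupling error to
  emitted quality is what gives the NQS filter genuine discriminating work.
* **5′ ends are exact**: no 5′ isomiRs are simulated; the analysis anchors 5′
  ends, and 5′ variation is out of scope.
* **Determinism**: all randomness flows from `SimulationConfig.seed`;
  per-library seeds derive from it via `numpy.random.SeedSequence` spawn
  keys, so the whole experiment is byte-reproducible.

What the simulator does **not** model: ligation/PCR bias, PCR duplicates,
non-miRNA small RNAs, indels, pre-miRNA (precursor) uridylation, 5′ isomiRs,
and cross-mapping between genuine miRNA families (catalog sequences are
drawn with pairwise prefix Hamming distance ≥ 3 unless ambiguous families are
requested). Passing tests therefore demonstrate correctness of the
*computational* chain and its statistical calibration under the assumed
generative model — not robustness to every artifact of real libraries.

## Problem sizes used by the tests and the acceptance script

The simulated scales are chosen as desk-scale stand-ins that preserve the
statistical regime of a real study: the knockout-recovery experiment uses 3
pairs × 50 miRNAs × 200,000 reads/library (per-miRNA counts large enough
that the waterfall CI is a few tenths of a log₂ unit wide); null calibration
uses 200 replicates of a smaller design (10 miRNAs × 2,500 reads, with
tailing ranges raised to 8–20 % so per-library modified counts stay in the
tens and the t-test's normality assumption is honest); the species-count
comparison uses 150 miRNAs at 30,000 reads with per-miRNA uridylation of
0.2–2 %, putting expected per-library unambiguous-U events near 1 — the
regime where the every-library detection requirement is sensitive to a
knockout. At saturating depth every species is detected in both genotypes
and the species counts are uninformative, which the full-depth analysis
scripts display honestly.

## Known limitations

* "Perfect adapter match" is exact string matching; a single error in the
  adapter region discards the read (≈ 2–3 % at 0.1 % per-base error with a
  27-nt adapter), which mirrors a strict barcode-sorting rule rather than
  error-tolerant demultiplexing.
* The 3′-end mismatch window (terminal 5 nt) is one defensible reading of a
  "5 at the 3′ end" budget; other window conventions would shift internal/3′
  classification for heavily mutated reads but not the +1 tail calls
  themselves.
* The waterfall pseudocount (half a read, as a percent) is one of several
  reasonable zero-handling rules; it is exposed in the code and its effect
  vanishes for miRNAs passing the WT percent filter except through
  occasional zero-percent KO libraries.
* The species χ² is a goodness-of-fit on the two genotype counts; if many
  species are shared the two counts are not independent samples, so the test
  is an approximation — the same construction as the printed analysis it
  reproduces.
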