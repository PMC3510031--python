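"""Seeded simulator of paired wild-type/knockout small-RNA libraries.

The generator emulates the statistical structure the downstream analysis
assumes: a catalog of mature miRNAs (20-23 nt) with genomic 3' flanks,
log-normal expression, per-miRNA probabilities of mono/oligo-uridylation and
adenylation with geometrically decaying tail lengths (1-4 nt), a knockout
genotype whose U-tailing probability is scaled by a multiplicative factor
(adenylation unchanged by default), barcode-bearing 3' adapters for
multiplexing, and substitution sequencing errors whose emitted quality scores
are drawn from a low-quality model so that neighborhood-quality filtering has
real work to do.

Every read carries a truth annotation (source miRNA, true tail, error
positions) sufficient to reconstruct the emitted sequence exactly, which the
test suite uses as ground truth for round-trip and parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import SmallRNARead, write_fastq
from .refcat import MiRNARefEntry

__all__ = [
    "SimulationConfig",
    "SimulatedLibrary",
    "generate_reference",
    "simulate_library",
    "simulate_experiment",
    "library_seed",
]

_BASES = np.array(list("ACGT"))

# Illumina-style 6-nt index barcodes; pairwise non-prefix and dissimilar.
DEFAULT_BARCODES = ("ATCACG", "CGATGT", "TTAGGC", "TGACCA")
DEFAULT_ADAPTER3_CORE = "TCGTATGCCGTCTTCTGCTTG"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the simulated sequencing study.

    Defaults emulate the structure of a three-pair liver small-RNA study:
    three WT/KO library pairs, four 3'-adapter barcodes, miRNA-dominated
    inserts under 30 nt with U/A tails of 1-4 nt, and a knockout that tails
    with U at 0.3x the wild-type probability while adenylation is unchanged.
    """

    n_mirnas: int = 50
    mature_length_range: tuple[int, int] = (20, 23)
    expression_logmean: float = 0.0
    expression_logsd: float = 1.0
    u_tail_prob_range: tuple[float, float] = (0.01, 0.10)
    a_tail_prob_range: tuple[float, float] = (0.01, 0.06)
    tail_length_decay: float = 0.45
    ko_u_factor: float = 0.3
    ko_a_factor: float = 1.0
    frac_templated_t_flank: float = 0.25
    per_base_error_rate: float = 0.001
    quality_mean: float = 34.0
    quality_sd: float = 3.0
    error_quality_mean: float = 12.0
    error_quality_sd: float = 4.0
    depth_per_library: int = 200_000
    n_pairs: int = 3
    barcodes: tuple[str, ...] = DEFAULT_BARCODES
    adapter3_core: str = DEFAULT_ADAPTER3_CORE
    flank_len: int = 12
    min_pairwise_hamming: int = 3
    allow_similar_matures: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be positive")
        if self.depth_per_library < 0:
            raise ValueError("depth_per_library must be >= 0")
        for name in ("u_tail_prob_range", "a_tail_prob_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi <= 1")
        if not 0.0 < self.tail_length_decay < 1.0:
            raise ValueError("tail_length_decay must be in (0, 1)")
        if not 0.0 <= self.frac_templated_t_flank <= 1.0:
            raise ValueError("frac_templated_t_flank must be in [0, 1]")
        if not 0.0 <= self.per_base_error_rate <= 1.0:
            raise ValueError("per_base_error_rate must be in [0, 1]")
        if self.ko_u_factor <= 0 or self.ko_a_factor <= 0:
            raise ValueError("knockout factors must be > 0")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be distinct")
        for a in self.barcodes:
            for b in self.barcodes:
                if a != b and b.startswith(a):
                    raise ValueError(f"barcode {a!r} is a prefix of {b!r}")

    @property
    def adapters(self) -> tuple[str, ...]:
        """Full 3' adapter per barcode: index barcode followed by the core."""
        return tuple(bc + self.adapter3_core for bc in self.barcodes)

    @property
    def tail_length_pmf(self) -> np.ndarray:
        """P(tail length = 1..4), geometric decay, truncated and normalized."""
        w = self.tail_length_decay ** np.arange(4)
        return w / w.sum()


@dataclass
class SimulatedLibrary:
    """One simulated library: reads plus per-read truth annotations."""

    library_id: str
    genotype: str
    barcode_index: int
    reads: list[SmallRNARead]
    truth: pd.DataFrame  # read_id, mirna, tail, n_errors, error_pos, error_obs


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, length)])


def _prefix_hamming(a: str, b: str) -> int:
    n = min(len(a), len(b))
    return sum(1 for i in range(n) if a[i] != b[i])


def generate_reference(
    config: SimulationConfig,
) -> tuple[list[MiRNARefEntry], pd.DataFrame]:
    """Draw the miRNA catalog and its ground-truth table.

    Mature sequences are unique and pairwise distinguishable (Hamming
    distance over the common 5' prefix >= ``min_pairwise_hamming``) unless
    ``allow_similar_matures`` requests ambiguous families.  Exactly
    ``round(frac_templated_t_flank * n_mirnas)`` flanks begin with T, creating
    miRNAs whose +1 U reads are genomically templated and must not be called.
    """
    rng = np.random.default_rng(config.seed)
    lmin, lmax = config.mature_length_range
    if lmin < 1 or lmax < lmin:
        raise ValueError("invalid mature_length_range")

    matures: list[str] = []
    max_attempts = 2000
    for i in range(config.n_mirnas):
        for attempt in range(max_attempts):
            length = int(rng.integers(lmin, lmax + 1))
            cand = _random_seq(rng, length)
            if config.allow_similar_matures:
                ok = cand not in matures
            else:
                ok = all(
                    _prefix_hamming(cand, m) >= config.min_pairwise_hamming
                    for m in matures
                )
            if ok:
                matures.append(cand)
                break
        else:
            raise ValueError(
                f"could not draw {config.n_mirnas} pairwise-distinguishable "
                f"mature sequences of length {lmin}-{lmax}"
            )

    n_t = round(config.frac_templated_t_flank * config.n_mirnas)
    t_idx = set(rng.choice(config.n_mirnas, size=n_t, replace=False).tolist())
    flanks = []
    for i in range(config.n_mirnas):
        rest = _random_seq(rng, config.flank_len - 1)
        if i in t_idx:
            flanks.append("T" + rest)
        else:
            first = "ACG"[rng.integers(0, 3)]
            flanks.append(first + rest)

    abundance = rng.lognormal(config.expression_logmean, config.expression_logsd,
                              config.n_mirnas)
    abundance /= abundance.sum()
    u_lo, u_hi = config.u_tail_prob_range
    a_lo, a_hi = config.a_tail_prob_range
    u_prob = rng.uniform(u_lo, u_hi, config.n_mirnas)
    a_prob = rng.uniform(a_lo, a_hi, config.n_mirnas)

    width = len(str(config.n_mirnas))
    names = [f"sim-mir-{i + 1:0{width}d}" for i in range(config.n_mirnas)]
    catalog = [
        MiRNARefEntry(name=n, mature_seq=m, flank3=f, source="simulated")
        for n, m, f in zip(names, matures, flanks)
    ]
    pmf = config.tail_length_pmf
    truth = pd.DataFrame(
        {
            "name": names,
            "mature_seq": matures,
            "flank3": flanks,
            "abundance": abundance,
            "u_prob_wt": u_prob,
            "a_prob_wt": a_prob,
            "u_prob_ko": np.clip(u_prob * config.ko_u_factor, 0.0, 1.0),
            "a_prob_ko": np.clip(a_prob * config.ko_a_factor, 0.0, 1.0),
            **{f"p_tail_len_{k}": pmf[k - 1] for k in (1, 2, 3, 4)},
        }
    )
    return catalog, truth


def simulate_library(
    catalog: list[MiRNARefEntry],
    truth: pd.DataFrame,
    genotype: str,
    barcode_index: int,
    depth: int,
    seed: int,
    config: SimulationConfig,
    library_id: str | None = None,
) -> SimulatedLibrary:
    """Simulate one library of ``depth`` reads for one genotype and barcode.

    Each read is mature + (optional homopolymer U or A tail) + the
    barcode-bearing 3' adapter, with substitution errors at
    ``per_base_error_rate``.  Error positions receive quality scores from the
    low-quality model; all other bases from the main model.
    """
    if genotype not in ("WT", "KO"):
        raise ValueError(f"unknown genotype {genotype!r}; expected 'WT' or 'KO'")
    if not 0 <= barcode_index < len(config.barcodes):
        raise ValueError(f"barcode_index {barcode_index} out of range")
    library_id = library_id or f"{genotype}{barcode_index}"
    rng = np.random.default_rng(seed)
    adapter = config.adapters[barcode_index]

    matures = truth["mature_seq"].to_numpy()
    u_col = "u_prob_wt" if genotype == "WT" else "u_prob_ko"
    a_col = "a_prob_wt" if genotype == "WT" else "a_prob_ko"
    pu = truth[u_col].to_numpy()
    pa = truth[a_col].to_numpy()
    names = truth["name"].to_numpy()

    if depth == 0:
        empty = pd.DataFrame(
            columns=["read_id", "library_id", "mirna", "tail", "n_errors",
                     "error_pos", "error_obs"]
        )
        return SimulatedLibrary(library_id, genotype, barcode_index, [], empty)

    idx = rng.choice(len(matures), size=depth, p=truth["abundance"].to_numpy())
    u = rng.random(depth)
    is_u = u < pu[idx]
    is_a = ~is_u & (u < pu[idx] + pa[idx])
    tail_len = np.where(
        is_u | is_a, rng.choice([1, 2, 3, 4], size=depth, p=config.tail_length_pmf), 0
    )
    mature_lens = np.array([len(m) for m in matures])[idx]
    read_lens = mature_lens + tail_len + len(adapter)
    offsets = np.concatenate([[0], np.cumsum(read_lens)])
    total = int(offsets[-1])

    quals = np.clip(
        np.rint(rng.normal(config.quality_mean, config.quality_sd, total)), 2, 40
    ).astype(np.uint8)
    err_mask = rng.random(total) < config.per_base_error_rate
    n_err = int(err_mask.sum())
    err_shift = rng.integers(1, 4, n_err)  # substitution: +1..3 in base space
    err_quals = np.clip(
        np.rint(rng.normal(config.error_quality_mean, config.error_quality_sd, n_err)),
        2, 40,
    ).astype(np.uint8)
    quals[err_mask] = err_quals

    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    reads: list[SmallRNARead] = []
    rows = []
    err_cursor = 0
    for i in range(depth):
        j = int(idx[i])
        tail = ("T" if is_u[i] else "A") * int(tail_len[i]) if tail_len[i] else ""
        template = matures[j] + tail + adapter
        lo, hi = int(offsets[i]), int(offsets[i + 1])
        mask = err_mask[lo:hi]
        read_id = f"{library_id}:{i:07d}"
        if mask.any():
            chars = list(template)
            pos_list = np.flatnonzero(mask)
            obs = []
            for p in pos_list:
                new = _BASES[(base_index[chars[p]] + int(err_shift[err_cursor])) % 4]
                err_cursor += 1
                chars[p] = new
                obs.append(new)
            seq = "".join(chars)
            rows.append(
                (read_id, library_id, names[j], tail, len(pos_list),
                 ";".join(map(str, pos_list)), ";".join(obs))
            )
        else:
            seq = template
            rows.append((read_id, library_id, names[j], tail, 0, "", ""))
        reads.append(
            SmallRNARead(read_id=read_id, sequence=seq, qualities=quals[lo:hi])
        )
    truth_df = pd.DataFrame(
        rows,
        columns=["read_id", "library_id", "mirna", "tail", "n_errors",
                 "error_pos", "error_obs"],
    )
    return SimulatedLibrary(library_id, genotype, barcode_index, reads, truth_df)


def library_seed(config_seed: int, pair: int, genotype: str) -> int:
    """Deterministic per-library seed derived from the experiment seed."""
    k = 2 * pair + (0 if genotype == "WT" else 1)
    ss = np.random.SeedSequence(entropy=config_seed, spawn_key=(k,))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_experiment(
    config: SimulationConfig, outdir: str | Path | None = None
) -> dict:
    """Simulate the full paired design: n_pairs x {WT, KO} libraries.

    Barcodes alternate across libraries (pair i: WT gets barcode 2i mod 4, KO
    gets 2i+1 mod 4), emulating four-plex multiplexing of a six-library study.
    Returns a dict with the catalog, truth table, libraries and pairing
    manifest; when ``outdir`` is given, also writes per-library FASTQ files,
    the truth/manifest/catalog TSVs and a config JSON.
    """
    catalog, truth = generate_reference(config)
    libraries: list[SimulatedLibrary] = []
    manifest_rows = []
    for pair in range(config.n_pairs):
        entry = {"pair_id": f"pair{pair + 1}"}
        for genotype in ("WT", "KO"):
            bc = (2 * pair + (0 if genotype == "WT" else 1)) % len(config.barcodes)
            lib_id = f"{genotype.lower()}{pair + 1}"
            lib = simulate_library(
                catalog, truth, genotype, bc, config.depth_per_library,
                seed=library_seed(config.seed, pair, genotype),
                config=config, library_id=lib_id,
            )
            libraries.append(lib)
            entry[f"{genotype.lower()}_library"] = lib_id
            entry[f"{genotype.lower()}_barcode_index"] = bc
            entry[f"{genotype.lower()}_fastq"] = f"{lib_id}.fastq"
        manifest_rows.append(entry)
    manifest = pd.DataFrame(manifest_rows)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for lib in libraries:
            write_fastq(lib.reads, outdir / f"{lib.library_id}.fastq")
        pd.concat([lib.truth for lib in libraries]).to_csv(
            outdir / "truth_reads.tsv", sep="\t", index=False
        )
        truth.to_csv(outdir / "truth_mirnas.tsv", sep="\t", index=False)
        manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
        with open(outdir / "mature.fa", "w") as fh:
            for e in catalog:
                fh.write(f">{e.name}\n{e.mature_seq}\n")
        with open(outdir / "flanks.tsv", "w") as fh:
            for e in catalog:
                fh.write(f"{e.name}\t{e.flank3}\n")

    return {
        "catalog": catalog,
        "truth": truth,
        "libraries": libraries,
        "manifest": manifest,
        "config": config,
    }
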