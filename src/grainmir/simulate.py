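"""Synthetic fixtures with known ground truth.

Everything downstream of sequencing is testable against simulated data:
a toy genome with planted miRNA hairpins, a small-RNA read population
with the bimodal 21/24-nt length structure characteristic of plant
libraries, contaminant reads drawn from an rRNA/tRNA-style catalog, and
three-stage, three-replicate chip signal tables with known up/down
regulation patterns.

All generators take one integer seed; per-operation substreams are
derived deterministically from it, so identical calls are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import canonical, revcomp, to_rna

STAGES = ("G1", "G2", "G3")

#: Read-length mixture observed in deep-sequenced grain small-RNA
#: libraries: 21-nt and 24-nt reads dominate (22.3% and 50.5%), the
#: remaining lengths in 18-26 nt share the rest uniformly.
DEFAULT_LENGTH_PROFILE = {
    18: 0.272 / 7, 19: 0.272 / 7, 20: 0.272 / 7,
    21: 0.223,
    22: 0.272 / 7, 23: 0.272 / 7,
    24: 0.505,
    25: 0.272 / 7, 26: 0.272 / 7,
}


@dataclass(frozen=True)
class PlantedHairpin:
    """A miRNA precursor planted in the synthetic genome.

    The precursor is mature arm + loop + star arm (order depending on
    ``mature_arm``); the star arm reverse-complements the mature arm
    except at deliberately mutated positions, so the excised window
    folds back into a stem-loop.
    """

    locus_id: str
    chrom: str
    start: int
    strand: str
    mature_seq: str  # RNA, 20-24 nt
    star_seq: str    # RNA, reverse complement of mature up to <=6 mutations
    loop_seq: str    # RNA, >=3 nt
    mature_arm: str  # '5p' or '3p'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.mature_arm not in ("5p", "3p"):
            raise ValueError(f"bad arm {self.mature_arm!r}")
        if not 20 <= len(self.mature_seq) <= 24:
            raise ValueError("mature_seq must be 20-24 nt")
        if len(self.loop_seq) < 3:
            raise ValueError("loop must be >=3 nt")
        mm = sum(a != b for a, b in zip(revcomp(canonical(self.mature_seq)),
                                        canonical(self.star_seq)))
        if mm > 6:
            raise ValueError("star arm diverges from mature by >6 positions")

    @property
    def precursor_rna(self) -> str:
        if self.mature_arm == "5p":
            return self.mature_seq + self.loop_seq + self.star_seq
        return self.star_seq + self.loop_seq + self.mature_seq

    @property
    def precursor_dna(self) -> str:
        return canonical(self.precursor_rna)

    @property
    def mature_offset(self) -> int:
        """0-based start of the mature arm on the precursor."""
        if self.mature_arm == "5p":
            return 0
        return len(self.star_seq) + len(self.loop_seq)


@dataclass(frozen=True)
class ReadLengthProfile:
    """Mixture over read lengths 18-26 nt; fractions sum to 1."""

    probabilities: dict[int, float]

    def __post_init__(self) -> None:
        for length in self.probabilities:
            if not 18 <= length <= 26:
                raise ValueError(f"length {length} outside 18-26")
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, not 1")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lengths = np.array(sorted(self.probabilities))
        probs = np.array([self.probabilities[l] for l in lengths])
        return rng.choice(lengths, size=n, p=probs)


@dataclass(frozen=True)
class ChipTruth:
    """Ground-truth expression program for one chip probe."""

    probe_id: str
    base_signal: float
    stage_multipliers: tuple[float, float, float]
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.stage_multipliers):
            raise ValueError("stage multipliers must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass
class SimulatedRead:
    sequence: str  # DNA
    category: str  # mature | star | contaminant | background
    locus_id: str | None = None


def _substream(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def random_hairpin(rng: np.random.Generator, locus_id: str, chrom: str,
                   start: int, strand: str = "+", mature_len: int = 21,
                   loop_len: int = 8, star_mutations: int = 0,
                   mature_arm: str = "5p") -> PlantedHairpin:
    """Draw a random planted hairpin spec.

    The star arm is the exact reverse complement of the mature arm with
    ``star_mutations`` random substitutions (<=6).
    """
    mature = _random_seq(rng, mature_len)
    star = list(revcomp(mature))
    if star_mutations:
        for pos in rng.choice(len(star), size=min(star_mutations, 6),
                              replace=False):
            star[pos] = rng.choice([b for b in "ACGT" if b != star[pos]])
    loop = _random_seq(rng, loop_len)
    return PlantedHairpin(
        locus_id=locus_id, chrom=chrom, start=start, strand=strand,
        mature_seq=to_rna(mature), star_seq=to_rna("".join(star)),
        loop_seq=to_rna(loop), mature_arm=mature_arm,
    )


def generate_genome(n_chroms: int, chrom_len: int,
                    hairpins: list[PlantedHairpin],
                    seed: int) -> tuple[dict[str, str], pd.DataFrame]:
    """Build a background genome and plant hairpin precursors into it.

    Background sequence is i.i.d. uniform over ACGT; each precursor
    (reverse-complemented for '-' strand loci) overwrites the background
    at its recorded coordinate.  Overlapping loci are rejected.

    Returns the genome as ``{chrom: sequence}`` plus a truth table with
    one row per planted locus.
    """
    rng = _substream(seed, 1)
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    genome = {name: list(_random_seq(rng, chrom_len)) for name in chrom_names}

    placed: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chrom_names}
    rows = []
    for hp in hairpins:
        if hp.chrom not in genome:
            raise ValueError(f"{hp.locus_id}: unknown chromosome {hp.chrom}")
        pre = hp.precursor_dna
        end = hp.start + len(pre)
        if hp.start < 0 or end > chrom_len:
            raise ValueError(f"{hp.locus_id}: precursor exceeds chromosome bounds")
        for (s, e, other) in placed[hp.chrom]:
            if hp.start < e and s < end:
                raise ValueError(
                    f"planted loci overlap: {hp.locus_id} and {other}")
        placed[hp.chrom].append((hp.start, end, hp.locus_id))
        inserted = pre if hp.strand == "+" else revcomp(pre)
        genome[hp.chrom][hp.start:end] = list(inserted)
        rows.append({
            "locus_id": hp.locus_id, "chrom": hp.chrom, "start": hp.start,
            "end": end, "strand": hp.strand,
            "mature_seq": canonical(hp.mature_seq),
            "star_seq": canonical(hp.star_seq),
            "precursor_seq": pre, "mature_arm": hp.mature_arm,
            "mature_offset": hp.mature_offset,
        })
    truth = pd.DataFrame(rows, columns=[
        "locus_id", "chrom", "start", "end", "strand", "mature_seq",
        "star_seq", "precursor_seq", "mature_arm", "mature_offset"])
    return {c: "".join(s) for c, s in genome.items()}, truth


def _shifted_mature(rng: np.random.Generator, hp: PlantedHairpin) -> str:
    """Mature read with uniform end shifts in {-2..+2}, drawn from the
    precursor so extensions use real flanking sequence."""
    pre = hp.precursor_dna
    s = hp.mature_offset
    e = s + len(canonical(hp.mature_seq))
    s2 = max(0, s + int(rng.integers(-2, 3)))
    e2 = min(len(pre), e + int(rng.integers(-2, 3)))
    if e2 - s2 < 18:
        return pre[s:e]
    return pre[s2:e2]


def simulate_reads(hairpins: list[PlantedHairpin],
                   profile: ReadLengthProfile,
                   n_reads: int,
                   mature_fraction: float = 0.0,
                   star_fraction: float = 0.0,
                   contaminant_fraction: float = 0.0,
                   contaminants: dict[str, str] | None = None,
                   isomir_rate: float = 0.0,
                   seed: int = 0) -> list[SimulatedRead]:
    """Draw a read population: planted mature/star reads, contaminant
    fragments, and random background reads.

    Category counts are a single multinomial draw, so they sum to
    ``n_reads`` exactly.  Background and contaminant read lengths follow
    ``profile``; mature/star reads keep their planted lengths (modulo
    optional +/-2-nt end shifts at rate ``isomir_rate``).
    """
    fracs = (mature_fraction, star_fraction, contaminant_fraction)
    if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1 + 1e-12:
        raise ValueError("category fractions must lie in [0,1] and sum <= 1")
    if (mature_fraction or star_fraction) and not hairpins:
        raise ValueError("mature/star reads requested but no hairpins given")
    if contaminant_fraction and not contaminants:
        raise ValueError("contaminant reads requested but no catalog given")

    rng = _substream(seed, 2)
    probs = [mature_fraction, star_fraction, contaminant_fraction]
    probs.append(max(0.0, 1.0 - sum(probs)))
    n_mat, n_star, n_cont, n_bg = rng.multinomial(n_reads, probs)

    reads: list[SimulatedRead] = []
    for _ in range(n_mat):
        hp = hairpins[int(rng.integers(len(hairpins)))]
        if isomir_rate and rng.random() < isomir_rate:
            seq = _shifted_mature(rng, hp)
        else:
            seq = canonical(hp.mature_seq)
        reads.append(SimulatedRead(seq, "mature", hp.locus_id))
    for _ in range(n_star):
        hp = hairpins[int(rng.integers(len(hairpins)))]
        reads.append(SimulatedRead(canonical(hp.star_seq), "star", hp.locus_id))
    if n_cont:
        names = sorted(contaminants)
        lengths = profile.sample(rng, n_cont)
        for length in lengths:
            name = names[int(rng.integers(len(names)))]
            src = canonical(contaminants[name])
            length = min(int(length), len(src))
            pos = int(rng.integers(0, len(src) - length + 1))
            reads.append(SimulatedRead(src[pos:pos + length], "contaminant", name))
    lengths = profile.sample(rng, n_bg)
    for length in lengths:
        reads.append(SimulatedRead(_random_seq(rng, int(length)), "background"))
    return reads


def write_fastq(reads: list[SimulatedRead], path) -> None:
    """Write reads as FASTQ with a fixed dummy Sanger quality ('#')."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@read{i}_{r.category}\n{r.sequence}\n+\n"
                     f"{'#' * len(r.sequence)}\n")


def simulate_chip(truths: list[ChipTruth], replicates: int = 3,
                  background_mean: float = 0.0, background_sd: float = 0.0,
                  seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate probe signals for three filling stages.

    Each (stage, replicate) pair is one chip.  A probe's raw signal is
    ``base_signal * stage_multiplier * lognormal(cv)`` plus the chip
    background (mean + Gaussian noise of the given SD).  Per-chip
    background statistics are returned alongside for the normalisation
    step.
    """
    if replicates < 2:
        raise ValueError("need >=2 replicates per stage")
    if background_sd < 0:
        raise ValueError("background_sd must be >= 0")
    rng = _substream(seed, 3)
    sig_rows, bg_rows = [], []
    for stage_i, stage in enumerate(STAGES):
        for rep in range(1, replicates + 1):
            bg_rows.append({"stage": stage, "replicate": rep,
                            "bg_mean": background_mean, "bg_sd": background_sd})
            for t in truths:
                mu = t.base_signal * t.stage_multipliers[stage_i]
                if t.noise_cv > 0:
                    sigma = np.sqrt(np.log1p(t.noise_cv ** 2))
                    noise = rng.lognormal(-sigma ** 2 / 2, sigma)
                else:
                    noise = 1.0
                bg = background_mean
                if background_sd > 0:
                    bg += rng.normal(0.0, background_sd)
                sig_rows.append({
                    "probe_id": t.probe_id, "stage": stage, "replicate": rep,
                    "signal": mu * noise + bg,
                })
    return pd.DataFrame(sig_rows), pd.DataFrame(bg_rows)


def default_contaminants(seed: int = 0, n: int = 8,
                         length: int = 120) -> dict[str, str]:
    """A small random catalog standing in for rRNA/tRNA/sno fragments."""
    rng = _substream(seed, 4)
    classes = ["rRNA", "tRNA", "snoRNA", "snRNA"]
    return {f"{classes[i % 4]}_{i}": _random_seq(rng, length)
            for i in range(n)}
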