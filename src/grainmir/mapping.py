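"""Exact, ungapped placement of collapsed reads on a reference genome.

Zero mismatches, no indels, both strands; reads hitting more loci than
``max_hits`` are flagged as multi-mapped and discarded, emulating a
repeat-reporting cap.  The index is a hash of fixed-length seeds with
verification extension — any exact-match strategy with the same
contract would do.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import canonical, revcomp
from .preprocess import SmallRead

SEED_LEN = 12


@dataclass(frozen=True)
class GenomeHit:
    read_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    strand: str


@dataclass(frozen=True)
class MappingSummary:
    unique_sequences: int
    aligned_sequences: int
    percent_aligned: float


class GenomeIndex:
    """Seed-and-extend exact substring index over a FASTA-style genome."""

    def __init__(self, genome: dict[str, str] | list[tuple[str, str]]):
        items = list(genome.items()) if isinstance(genome, dict) else list(genome)
        names = [c for c, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome name")
        self.genome = {c: canonical(s) for c, s in items}
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - SEED_LEN + 1):
                kmer = seq[i:i + SEED_LEN]
                if "N" in kmer:
                    continue
                self._seeds.setdefault(kmer, []).append((chrom, i))

    def occurrences(self, query: str) -> list[tuple[str, int]]:
        """All exact forward-strand occurrences of query (DNA, >= seed
        length), as (chrom, start) pairs."""
        query = canonical(query)
        if len(query) < SEED_LEN or "N" in query:
            return []
        hits = []
        for chrom, pos in self._seeds.get(query[:SEED_LEN], ()):
            if self.genome[chrom][pos:pos + len(query)] == query:
                hits.append((chrom, pos))
        return hits


def build_index(genome: dict[str, str]) -> GenomeIndex:
    return GenomeIndex(genome)


def map_read(read: SmallRead, index: GenomeIndex, max_hits: int = 20,
             read_id: str | None = None) -> tuple[list[GenomeHit], bool]:
    """All exact occurrences of the read on both strands.

    Returns (hits, multi_mapped_discarded); the hit list is empty when
    there are no occurrences or more than ``max_hits``.
    """
    seq = canonical(read.sequence)
    if not 18 <= len(seq) <= 26:
        raise ValueError("read length outside 18-26")
    rid = read_id if read_id is not None else seq
    hits = [GenomeHit(rid, c, p, p + len(seq), "+")
            for c, p in index.occurrences(seq)]
    rc = revcomp(seq)
    hits += [GenomeHit(rid, c, p, p + len(seq), "-")
             for c, p in index.occurrences(rc)]
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    if len(hits) > max_hits:
        return [], True
    return hits, False


def map_reads(reads: list[SmallRead], index: GenomeIndex,
              max_hits: int = 20) -> tuple[dict[str, list[GenomeHit]], set[str]]:
    """Map a collapsed read set; returns hits keyed by sequence plus
    the set of multi-mapped-discarded sequences."""
    hit_map: dict[str, list[GenomeHit]] = {}
    discarded: set[str] = set()
    for i, read in enumerate(reads):
        hits, multi = map_read(read, index, max_hits, read_id=f"seq{i + 1}")
        if multi:
            discarded.add(read.sequence)
        elif hits:
            hit_map[read.sequence] = hits
    return hit_map, discarded


def percent_aligned(aligned: int, unique: int) -> float:
    """Alignment rate as a percentage, one decimal place."""
    if unique == 0:
        raise ValueError("empty input")
    return round(100.0 * aligned / unique, 1)


def summarize(reads: list[SmallRead],
              hit_map: dict[str, list[GenomeHit]]) -> MappingSummary:
    unique = len(reads)
    aligned = sum(1 for r in reads if hit_map.get(r.sequence))
    return MappingSummary(unique, aligned, percent_aligned(aligned, unique))


def write_bed(reads: list[SmallRead], hit_map: dict[str, list[GenomeHit]],
              path) -> None:
    """Emit hits as 6-column BED (0-based half-open; score = read count)."""
    counts = {r.sequence: r.count for r in reads}
    with open(path, "w") as fh:
        for seq in sorted(hit_map):
            for h in hit_map[seq]:
                fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t{h.read_id}"
                         f"\t{counts.get(seq, 1)}\t{h.strand}\n")
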