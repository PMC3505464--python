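"""Novel miRNA discovery from mapped small reads.

For each mapped read not explained by the known catalog, genomic
windows extending 20-260 nt (13 extensions, 20-nt frame) upstream and
downstream of the read are excised and folded.  A candidate is accepted
when the fold supports a miRNA/miRNA* duplex — star arm located with a
2-nt 3' overhang, at most 6 mismatches and 3 bulges across the duplex —
and at least one sequenced read supports the star arm, the classic
evidence for genuine Dicer processing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from ._seq import revcomp, to_rna
from .fold import SecondaryStructure, fold
from .mapping import GenomeHit
from .preprocess import SmallRead

EXTENSIONS = tuple(range(20, 261, 20))  # 13 values
MAX_MISMATCHES = 6
MAX_BULGES = 3
STAR_PAIRED_FRACTION = 0.6
STAR_SHIFT = 2  # nt of 3' overhang on each duplex strand
END_TOLERANCE = 2  # +/- nt when matching reads to mature/star intervals


@dataclass(frozen=True)
class Window:
    """An excised genomic window, oriented so the read is in sense."""

    chrom: str
    start: int
    end: int
    strand: str
    seq: str          # RNA, sense orientation
    read_offset: int  # read start within seq

    def to_genomic(self, lo: int, hi: int) -> tuple[int, int]:
        """Map a window-coordinate interval back to genome coordinates."""
        if self.strand == "+":
            return self.start + lo, self.start + hi
        return self.end - hi, self.end - lo


@dataclass
class DuplexStats:
    mismatches: int
    bulges: int
    mature_interval: tuple[int, int]
    star_interval: tuple[int, int]


@dataclass
class HairpinCandidate:
    chrom: str
    start: int
    end: int
    strand: str
    mature_seq: str  # RNA
    precursor_seq: str  # RNA
    structure: SecondaryStructure
    duplex: DuplexStats
    mature_reads: int
    star_reads: int
    verdict: str
    context: str = "NA"


def excise_windows(hit: GenomeHit, genome: dict[str, str]) -> list[Window]:
    """Candidate precursor windows around one genomic hit: for each
    extension d in 20..260 step 20, one window reaching d nt upstream
    and one reaching d nt downstream of the read, clipped at chromosome
    bounds.  Minus-strand windows are reverse-complemented so the read
    reads 5'->3'."""
    chrom_seq = genome[hit.chrom]
    if hit.start < 0 or hit.end > len(chrom_seq):
        raise ValueError("hit beyond chromosome bounds")
    intervals = set()
    for d in EXTENSIONS:
        intervals.add((max(0, hit.start - d), hit.end))
        intervals.add((hit.start, min(len(chrom_seq), hit.end + d)))
    windows = []
    for ws, we in sorted(intervals):
        seq = chrom_seq[ws:we]
        if hit.strand == "+":
            offset = hit.start - ws
        else:
            seq = revcomp(seq)
            offset = we - hit.end
        windows.append(Window(hit.chrom, ws, we, hit.strand,
                              to_rna(seq), offset))
    return windows


def find_star(structure: SecondaryStructure,
              mature_interval: tuple[int, int],
              ) -> tuple[tuple[int, int] | None, str]:
    """Locate the miRNA* interval pairing with the mature interval.

    The partner span of the mature arm is shifted so each duplex strand
    carries a 2-nt 3' overhang.  Returns (interval, reason); interval is
    None when fewer than 60% of mature positions are paired, or the
    mature interval spans the hairpin loop.
    """
    ms, me = mature_interval
    part = structure.partner()
    n = len(part)
    paired = [i for i in range(ms, me) if part[i] >= 0]
    if len(paired) < STAR_PAIRED_FRACTION * (me - ms):
        return None, "unpaired"
    partners = [part[i] for i in paired]
    if any(ms <= p < me for p in partners):
        return None, "loop_spanning"
    if not (all(p >= me for p in partners) or all(p < ms for p in partners)):
        return None, "loop_spanning"
    # project through the majority antiparallel register: i + partner(i)
    # is constant along a clean stem, and the mode is robust to sloppy
    # pairing near the hairpin apex
    registers = Counter(part[i] + i for i in paired)
    top = max(registers.values())
    register = min(r for r, c in registers.items() if c == top)
    lo = register - (me - 1)
    hi = register - ms + 1
    lo, hi = lo + STAR_SHIFT, hi + STAR_SHIFT
    lo, hi = max(0, lo), min(n, hi)
    if hi <= lo:
        return None, "unpaired"
    if ms < hi and lo < me:
        return None, "overlaps_mature"
    return (lo, hi), "ok"


def duplex_stats(structure: SecondaryStructure,
                 mature_interval: tuple[int, int],
                 star_interval: tuple[int, int]) -> DuplexStats:
    """Count duplex imperfections between the mature and star arms.

    Paired columns anchor the duplex; between consecutive anchors,
    symmetric unpaired columns count as mismatches (one per column) and
    each asymmetric run of unpaired bases on a single strand counts as
    one bulge.  Terminal 3' overhangs are not penalised.
    """
    ms, me = mature_interval
    slo, shi = star_interval
    if ms < shi and slo < me:
        raise ValueError("mature and star intervals overlap")
    part = structure.partner()
    anchors = [(i, part[i]) for i in range(ms, me)
               if part[i] >= 0 and slo <= part[i] < shi]
    mismatches = 0
    bulges = 0
    for (i1, j1), (i2, j2) in zip(anchors, anchors[1:]):
        gap_m = i2 - i1 - 1
        gap_s = j1 - j2 - 1
        mismatches += min(gap_m, gap_s)
        if gap_m != gap_s:
            bulges += 1
    if not anchors:
        mismatches = me - ms
    return DuplexStats(mismatches, bulges, mature_interval, star_interval)


def call_candidate(stats: DuplexStats, star_reads: int,
                   known_mature: bool = False,
                   max_mismatches: int = MAX_MISMATCHES,
                   max_bulges: int = MAX_BULGES) -> str:
    """Accept or reject a candidate hairpin; rejection records why."""
    if known_mature:
        return "rejected:known"
    if stats.mismatches > max_mismatches:
        return "rejected:mismatches"
    if stats.bulges > max_bulges:
        return "rejected:bulges"
    if star_reads < 1:
        return "rejected:no_star"
    return "accepted"


def _reads_near(hit_map: dict[str, list[GenomeHit]],
                counts: dict[str, int], chrom: str, strand: str,
                lo: int, hi: int, tol: int = END_TOLERANCE) -> int:
    """Total read count whose hits land within +/-tol of an interval."""
    total = 0
    for seq, hits in hit_map.items():
        for h in hits:
            if (h.chrom == chrom and h.strand == strand
                    and abs(h.start - lo) <= tol and abs(h.end - hi) <= tol):
                total += counts[seq]
                break
    return total


def evaluate_hit(hit: GenomeHit, genome: dict[str, str],
                 hit_map: dict[str, list[GenomeHit]],
                 counts: dict[str, int],
                 known_mature: bool = False,
                 max_mismatches: int = MAX_MISMATCHES,
                 max_bulges: int = MAX_BULGES) -> HairpinCandidate | None:
    """Fold all windows around one hit and return the best accepted
    candidate (fewest mismatches+bulges, then shortest precursor), or
    None if no window supports a hairpin."""
    best: tuple[tuple[int, int], HairpinCandidate] | None = None
    mature_reads = _reads_near(hit_map, counts, hit.chrom, hit.strand,
                               hit.start, hit.end)
    for win in excise_windows(hit, genome):
        if len(win.seq) < 20 or len(win.seq) > 300:
            continue
        structure = fold(win.seq)
        m_iv = (win.read_offset, win.read_offset + (hit.end - hit.start))
        star_iv, _reason = find_star(structure, m_iv)
        if star_iv is None:
            continue
        stats = duplex_stats(structure, m_iv, star_iv)
        g_lo, g_hi = win.to_genomic(*star_iv)
        star_reads = _reads_near(hit_map, counts, hit.chrom, hit.strand,
                                 g_lo, g_hi)
        verdict = call_candidate(stats, star_reads, known_mature,
                                 max_mismatches, max_bulges)
        if verdict != "accepted":
            continue
        cand = HairpinCandidate(
            chrom=win.chrom, start=win.start, end=win.end, strand=win.strand,
            mature_seq=win.seq[m_iv[0]:m_iv[1]], precursor_seq=win.seq,
            structure=structure, duplex=stats, mature_reads=mature_reads,
            star_reads=star_reads, verdict=verdict)
        key = (stats.mismatches + stats.bulges, len(win.seq))
        if best is None or key < best[0]:
            best = (key, cand)
    return best[1] if best else None


def discover(reads: list[SmallRead],
             hit_map: dict[str, list[GenomeHit]],
             genome: dict[str, str],
             known_sequences: set[str] | None = None,
             min_read_count: int = 1,
             max_mismatches: int = MAX_MISMATCHES,
             max_bulges: int = MAX_BULGES) -> list[HairpinCandidate]:
    """Discover novel miRNA candidates from a mapped read set.

    Each mapped, non-known read anchors a window search; overlapping
    accepted candidates on one strand are merged, keeping the one with
    the most mature-read support (star-read anchors collapse onto their
    more abundant mature partner).
    """
    known = known_sequences or set()
    counts = {r.sequence: r.count for r in reads}
    candidates: list[HairpinCandidate] = []
    for read in reads:
        if read.sequence in known or read.count < min_read_count:
            continue
        for hit in hit_map.get(read.sequence, []):
            cand = evaluate_hit(hit, genome, hit_map, counts,
                                known_mature=False,
                                max_mismatches=max_mismatches,
                                max_bulges=max_bulges)
            if cand is not None:
                candidates.append(cand)

    # merge overlapping loci (either strand; the reverse complement of a
    # hairpin is a hairpin, and star anchors rediscover their own
    # precursor): highest mature support wins
    candidates.sort(key=lambda c: (-c.mature_reads, c.chrom, c.start,
                                   c.mature_seq))
    merged: list[HairpinCandidate] = []
    for cand in candidates:
        clash = any(c.chrom == cand.chrom
                    and c.start < cand.end and cand.start < c.end
                    for c in merged)
        if not clash:
            merged.append(cand)
    merged.sort(key=lambda c: (c.chrom, c.start))
    return merged


def write_candidates(candidates: list[HairpinCandidate], tsv_path,
                     structure_path=None) -> None:
    """Emit candidates as a TSV (name, sequence, length, abundance,
    chromosome, context) plus an optional FASTA-like structure file."""
    with open(tsv_path, "w") as fh:
        fh.write("name\tsequence\tlength\tabundance\tchromosome\tcontext\n")
        for i, c in enumerate(candidates, start=1):
            fh.write(f"Can_miR_{i:02d}\t{c.mature_seq}\t{len(c.mature_seq)}"
                     f"\t{c.mature_reads}\t{c.chrom}\t{c.context}\n")
    if structure_path is not None:
        with open(structure_path, "w") as fh:
            for i, c in enumerate(candidates, start=1):
                fh.write(f">Can_miR_{i:02d} {c.chrom}:{c.start}-{c.end}"
                         f"({c.strand})\n{c.precursor_seq}\n"
                         f"{c.structure.dotbracket}\n")
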