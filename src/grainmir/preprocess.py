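"""Raw small-RNA read cleanup.

Adapter trimming, the 18-26 nt length window, contaminant removal by
exact substring match against an rRNA/tRNA/sno catalog, and collapsing
to unique sequences with counts.  Every removed read is attributed to
exactly one removal class so the accounting identity

    raw = clean + no_adapter + empty + short + long + ambiguous + contaminant

holds for every run.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio import SeqIO

from ._seq import canonical, revcomp


@dataclass(frozen=True)
class SmallRead:
    """A collapsed unique read sequence with its copy count."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass
class PreprocessReport:
    raw_reads: int = 0
    clean_reads: int = 0
    unique_sequences: int = 0
    contaminant_reads: int = 0
    removed: Counter = field(default_factory=Counter)
    length_histogram: Counter = field(default_factory=Counter)

    def to_dict(self) -> dict:
        return {
            "raw_reads": self.raw_reads,
            "clean_reads": self.clean_reads,
            "unique_sequences": self.unique_sequences,
            "contaminant_reads": self.contaminant_reads,
            "removed": dict(self.removed),
            "length_histogram": {int(k): v for k, v in
                                 sorted(self.length_histogram.items())},
        }


class TrimRejection(Exception):
    """Read rejected during adapter trimming; .reason says why."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


def trim_adapter(read: str, adapter: str, min_overlap: int = 6) -> str:
    """Remove the 3' adapter from a read.

    The insert ends at the leftmost position where a prefix of the
    adapter matches the read exactly over at least ``min_overlap``
    bases (a shorter match is allowed only when the read ends before
    the adapter does).  Reads with no adapter occurrence are rejected:
    with a fixed-length sequencing cycle a genuine small-RNA insert
    always runs into the adapter.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 5:
        raise ValueError("min_overlap must be >= 5")
    read = canonical(read)
    adapter = canonical(adapter)
    if not read:
        raise TrimRejection("empty")
    for i in range(len(read)):
        tail = read[i:]
        k = min(len(tail), len(adapter))
        if k >= min_overlap and tail[:k] == adapter[:k]:
            if i == 0:
                raise TrimRejection("empty_insert")
            return read[:i]
    raise TrimRejection("no_adapter")


def filter_reads(reads: list[str], min_len: int = 18, max_len: int = 26,
                 contaminants: dict[str, str] | None = None,
                 ) -> tuple[list[str], Counter]:
    """Drop reads outside the length window, reads containing N, and
    reads occurring as exact substrings of any contaminant sequence on
    either strand.  Returns retained reads plus removal-class tallies."""
    catalog = []
    for seq in (contaminants or {}).values():
        seq = canonical(seq)
        catalog.append(seq)
        catalog.append(revcomp(seq))
    kept: list[str] = []
    removed: Counter = Counter()
    for read in reads:
        read = canonical(read)
        if len(read) < min_len:
            removed["short"] += 1
        elif len(read) > max_len:
            removed["long"] += 1
        elif "N" in read:
            removed["ambiguous"] += 1
        elif any(read in c for c in catalog):
            removed["contaminant"] += 1
        else:
            kept.append(read)
    return kept, removed


def collapse(reads: list[str]) -> list[SmallRead]:
    """Collapse reads to unique sequences, sorted by descending count
    with lexicographic tie-break; total count is conserved."""
    counts = Counter(canonical(r) for r in reads)
    return [SmallRead(seq, n)
            for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]


def preprocess(reads: list[str], adapter: str | None = None,
               min_overlap: int = 6, min_len: int = 18, max_len: int = 26,
               contaminants: dict[str, str] | None = None,
               ) -> tuple[list[SmallRead], PreprocessReport]:
    """Full cleanup: (optional) adapter trim -> length/contaminant
    filter -> collapse.  Pass ``adapter=None`` for pre-trimmed input."""
    report = PreprocessReport(raw_reads=len(reads))
    trimmed: list[str] = []
    for read in reads:
        if adapter is None:
            trimmed.append(canonical(read))
            continue
        try:
            trimmed.append(trim_adapter(read, adapter, min_overlap))
        except TrimRejection as rej:
            report.removed[rej.reason] += 1
    kept, removed = filter_reads(trimmed, min_len, max_len, contaminants)
    report.removed.update(removed)
    report.contaminant_reads = removed.get("contaminant", 0)
    report.clean_reads = len(kept)
    report.length_histogram = Counter(len(r) for r in kept)
    collapsed = collapse(kept)
    report.unique_sequences = len(collapsed)
    return collapsed, report


def read_sequences(path) -> list[str]:
    """Load read sequences from FASTA or FASTQ (sniffed from the first
    character), canonicalised to uppercase DNA."""
    with open(path) as fh:
        head = fh.read(1)
    fmt = "fastq" if head == "@" else "fasta"
    return [canonical(str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]


def write_collapsed_fasta(reads: list[SmallRead], path) -> None:
    """Write collapsed reads as ``>seq<rank>_x<count>`` FASTA."""
    with open(path, "w") as fh:
        for rank, r in enumerate(reads, start=1):
            fh.write(f">seq{rank}_x{r.count}\n{r.sequence}\n")
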