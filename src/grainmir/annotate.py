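"""Assignment of reads to known mature miRNAs.

Reads are compared gaplessly against each catalog precursor within
+/-2 nt of the annotated mature ends, tolerating up to 2 substitutions
and no indels — the standard treatment of positional variants
(isomiRs) produced by imprecise Dicer cleavage.  Reads landing on the
arm opposite the annotated mature arm are flagged as miRNA* and
tallied separately.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from ._seq import canonical
from .fold import SecondaryStructure, fold
from .preprocess import SmallRead

MAX_MISMATCHES = 2
MAX_SHIFT = 2


@dataclass(frozen=True)
class MatureMiRNARecord:
    name: str
    sequence: str          # DNA space
    precursor_id: str
    offset_on_precursor: int
    arm: str               # '5p' or '3p'


@dataclass(frozen=True)
class MatureMatch:
    read_id: str
    mirna_name: str
    mismatches: int
    shift5: int
    shift3: int
    is_star: bool = False


class Catalog:
    """Known-miRNA catalog: mature records anchored on precursors."""

    def __init__(self, matures: list[MatureMiRNARecord],
                 precursors: dict[str, str]):
        self.precursors = {k: canonical(v) for k, v in precursors.items()}
        self.matures = matures
        for rec in matures:
            pre = self.precursors.get(rec.precursor_id)
            if pre is None:
                raise ValueError(f"{rec.name}: unknown precursor "
                                 f"{rec.precursor_id}")
            end = rec.offset_on_precursor + len(rec.sequence)
            if pre[rec.offset_on_precursor:end] != rec.sequence:
                raise ValueError(f"{rec.name}: sequence does not occur at "
                                 "its annotated precursor offset")

    def mature_arm_of(self, precursor_id: str) -> str | None:
        """Arm carrying the primary (non-star) mature annotation."""
        for rec in self.matures:
            if rec.precursor_id == precursor_id and not rec.name.endswith("*"):
                return rec.arm
        return None


def load_catalog(mature_fasta, precursor_fasta, links_tsv) -> Catalog:
    """Load a catalog from mature + precursor FASTA and a TSV linking
    mature name -> (precursor_id, offset, arm)."""
    mature_seqs = {r.id: canonical(str(r.seq))
                   for r in SeqIO.parse(str(mature_fasta), "fasta")}
    precursors = {r.id: canonical(str(r.seq))
                  for r in SeqIO.parse(str(precursor_fasta), "fasta")}
    links = pd.read_csv(links_tsv, sep="\t")
    matures = [MatureMiRNARecord(row["name"], mature_seqs[row["name"]],
                                 row["precursor_id"], int(row["offset"]),
                                 row["arm"])
               for _, row in links.iterrows()]
    return Catalog(matures, precursors)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def match_to_catalog(read: SmallRead, catalog: Catalog,
                     read_id: str | None = None) -> MatureMatch | None:
    """Best gapless assignment of a read to a catalog mature miRNA.

    Candidate placements are the precursor windows starting within
    +/-2 nt of each annotated mature start and ending within +/-2 nt of
    its end; the best is the fewest mismatches, then the smallest total
    end shift, then the lexicographically first miRNA name.  None when
    every placement needs more than 2 substitutions.
    """
    seq = canonical(read.sequence)
    rid = read_id if read_id is not None else seq
    best: tuple[tuple[int, int, str], MatureMatch] | None = None
    for rec in catalog.matures:
        pre = catalog.precursors[rec.precursor_id]
        m_len = len(rec.sequence)
        for shift5 in range(-MAX_SHIFT, MAX_SHIFT + 1):
            shift3 = len(seq) - m_len + shift5
            if abs(shift3) > MAX_SHIFT:
                continue
            start = rec.offset_on_precursor + shift5
            end = rec.offset_on_precursor + m_len + shift3
            if start < 0 or end > len(pre):
                continue
            mm = _hamming(seq, pre[start:end])
            if mm > MAX_MISMATCHES:
                continue
            key = (mm, abs(shift5) + abs(shift3), rec.name)
            if best is None or key < best[0]:
                best = (key, MatureMatch(rid, rec.name, mm, shift5, shift3))
    return best[1] if best else None


def assign_star(match: MatureMatch, catalog: Catalog,
                structure: SecondaryStructure | None = None) -> bool | None:
    """Flag a match as miRNA* when it lies on the arm opposite the
    precursor's annotated mature arm.

    The precursor is folded (or a pre-computed structure passed in) to
    locate the hairpin loop; reads spanning the loop, or precursors
    that fold without a stem, give None (undetermined).
    """
    rec = next(r for r in catalog.matures if r.name == match.mirna_name)
    pre = catalog.precursors[rec.precursor_id]
    mature_arm = catalog.mature_arm_of(rec.precursor_id)
    if mature_arm is None:
        return None
    if structure is None:
        structure = fold(pre, min_len=20, max_len=300)
    part = structure.partner()
    pairs = [(i, part[i]) for i in range(len(part)) if part[i] > i]
    if not pairs:
        return None
    # hairpin loop = interior of the innermost pair of the main stem
    loop_lo, loop_hi = min(pairs, key=lambda p: p[1] - p[0])
    start = rec.offset_on_precursor + match.shift5
    end = rec.offset_on_precursor + len(rec.sequence) + match.shift3
    if end <= loop_lo + 1:
        side = "5p"
    elif start > loop_hi - 1:
        side = "3p"
    else:
        return None  # loop-spanning
    return side != mature_arm


def family_name(mirna_name: str) -> str:
    """Collapse member/arm/variant suffixes to the family name:
    miR159a.2 -> miR159, miR444b.2 -> miR444, miR1874-5p -> miR1874,
    *miR1867 -> miR1867, miR160a-d -> miR160."""
    name = mirna_name.lstrip("*")
    m = re.search(r"(miR\d+)", name, flags=re.IGNORECASE)
    return m.group(1) if m else name


def annotate_reads(reads: list[SmallRead], catalog: Catalog,
                   ) -> dict[str, MatureMatch]:
    """Match every collapsed read; star flags are filled in from the
    folded precursors.  Keyed by read sequence."""
    matches: dict[str, MatureMatch] = {}
    for i, read in enumerate(reads):
        m = match_to_catalog(read, catalog, read_id=f"seq{i + 1}")
        if m is None:
            continue
        star = assign_star(m, catalog)
        matches[read.sequence] = MatureMatch(
            m.read_id, m.mirna_name, m.mismatches, m.shift5, m.shift3,
            is_star=bool(star) if star is not None else False)
    return matches


def family_table(matches: dict[str, MatureMatch],
                 reads: list[SmallRead]) -> pd.DataFrame:
    """Per-miRNA and per-family read counts (read copies, not unique
    sequences), with miRNA* copies tallied separately."""
    counts = {r.sequence: r.count for r in reads}
    rows: dict[str, dict] = {}
    for seq, m in matches.items():
        row = rows.setdefault(m.mirna_name, {
            "mirna": m.mirna_name, "family": family_name(m.mirna_name),
            "reads": 0, "star_reads": 0})
        if m.is_star:
            row["star_reads"] += counts[seq]
        else:
            row["reads"] += counts[seq]
    if not rows:
        return pd.DataFrame(columns=["mirna", "family", "reads", "star_reads"])
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: r["mirna"]))
    return df
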