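"""Plant miRNA target-site scoring.

A miRNA is slid (as its reverse complement) along each transcript and
every near-contiguous site is scored with additive penalties: 1.0 per
mismatch, 0.5 per G:U wobble, 2.0 per gapped position, with at most one
single-base gap per site.  A perfect site scores 0; sites above the
score ceiling (default 5.0) are discarded.  Degradome/RACE clone 5'
ends can be mapped onto an alignment to profile cleavage positions.

Pairing-string codes: '|' Watson-Crick match, 'o' G:U wobble,
'x' mismatch, '-' gap (on either strand).
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import canonical, is_watson_crick, is_wobble

PENALTY = {"|": 0.0, "o": 0.5, "x": 1.0, "-": 2.0}


@dataclass(frozen=True)
class TargetAlignment:
    mirna_name: str
    transcript_id: str
    site_start: int          # 0-based on transcript
    site_end: int            # exclusive
    pairing: str             # codes over alignment columns, miRNA 5'->3'
    score: float
    gap_on: str | None = None  # 'mirna' | 'transcript' | None


@dataclass
class CleavageProfile:
    alignment: TargetAlignment
    position_counts: dict[int, int]
    off_target_clones: int


def score_alignment(pairing: str) -> float:
    """Penalty of a pairing string; unknown codes are an error."""
    total = 0.0
    for c in pairing:
        if c not in PENALTY:
            raise ValueError(f"unknown pairing code {c!r}")
        total += PENALTY[c]
    return total


def _classify(m_base: str, t_base: str) -> str:
    """Pairing class of one miRNA base facing one transcript base:
    Watson-Crick pair, G:U wobble (miRNA G : target U, or miRNA U :
    target G), or mismatch."""
    if is_watson_crick(m_base, t_base):
        return "|"
    if is_wobble(m_base, t_base):
        return "o"
    return "x"


def _pairing_codes(mirna: str, target_rc_order: str) -> str:
    """Column codes for an ungapped miRNA-vs-site comparison.

    ``target_rc_order`` is the transcript site reversed so that column
    k faces miRNA position k (miRNA 5' end pairs the site's 3' end).
    """
    return "".join(_classify(m, t) for m, t in zip(mirna, target_rc_order))


def _site_alignments(mirna: str, transcript: str, start: int):
    """All alignments of the miRNA beginning at transcript ``start``
    (site 3' end fixed there... see scan_transcript): ungapped plus
    every single-gap placement."""
    L = len(mirna)
    n = len(transcript)
    # ungapped: site covers [start, start+L)
    if start + L <= n:
        site = transcript[start:start + L][::-1]
        yield _pairing_codes(mirna, site), start, start + L, None
    # one unpaired transcript base (gap in the miRNA row): site L+1 long
    if start + L + 1 <= n:
        site = transcript[start:start + L + 1][::-1]
        for g in range(1, L):  # no terminal gaps
            codes = _pairing_codes(mirna[:g], site[:g]) + "-" + \
                _pairing_codes(mirna[g:], site[g + 1:])
            yield codes, start, start + L + 1, "mirna"
    # one unpaired miRNA base (gap in the transcript row): site L-1 long
    if start + L - 1 <= n:
        site = transcript[start:start + L - 1][::-1]
        for g in range(1, L - 1):
            codes = _pairing_codes(mirna[:g], site[:g]) + "-" + \
                _pairing_codes(mirna[g + 1:], site[g:])
            yield codes, start, start + L - 1, "transcript"


def scan_transcript(mirna: str, transcript: str, max_score: float = 5.0,
                    mirna_name: str = "miRNA",
                    transcript_id: str = "transcript",
                    ) -> list[TargetAlignment]:
    """All target sites of a miRNA on a transcript scoring at or below
    ``max_score``, sorted by ascending score then position.  Transcripts
    shorter than the miRNA yield an empty list."""
    mirna = canonical(mirna)
    if not 18 <= len(mirna) <= 26:
        raise ValueError("miRNA length outside 18-26 nt")
    transcript = canonical(transcript)
    if len(transcript) < len(mirna):
        return []
    hits = []
    seen = set()
    for start in range(len(transcript)):
        best_here: dict[tuple[int, int], tuple[float, str, str | None]] = {}
        for codes, s, e, gap_on in _site_alignments(mirna, transcript, start):
            score = score_alignment(codes)
            if score > max_score:
                continue
            key = (s, e)
            if key not in best_here or score < best_here[key][0]:
                best_here[key] = (score, codes, gap_on)
        for (s, e), (score, codes, gap_on) in best_here.items():
            if (s, e) in seen:
                continue
            seen.add((s, e))
            hits.append(TargetAlignment(mirna_name, transcript_id, s, e,
                                        codes, score, gap_on))
    hits.sort(key=lambda a: (a.score, a.site_start, a.site_end))
    return hits


def map_clones(alignment: TargetAlignment,
               clone_5p_ends: list[int]) -> CleavageProfile:
    """Convert degradome/RACE clone 5' ends (transcript offsets) to
    1-based positions counted from the miRNA 5' end.

    The miRNA 5' end faces the 3' end of the site, so transcript
    position t inside [site_start, site_end) maps to miRNA position
    ``site_end - t``.  Ends outside the site count as off-target.
    """
    counts: dict[int, int] = {}
    off = 0
    for t in clone_5p_ends:
        if alignment.site_start <= t < alignment.site_end:
            pos = alignment.site_end - t
            counts[pos] = counts.get(pos, 0) + 1
        else:
            off += 1
    return CleavageProfile(alignment, counts, off)


def scan_many(mirnas: dict[str, str], transcripts: dict[str, str],
              max_score: float = 5.0) -> list[TargetAlignment]:
    out = []
    for m_name in sorted(mirnas):
        for t_name in sorted(transcripts):
            out.extend(scan_transcript(mirnas[m_name], transcripts[t_name],
                                       max_score, m_name, t_name))
    return out


def write_targets(alignments: list[TargetAlignment], path) -> None:
    """TSV report; start is 1-based for reporting."""
    with open(path, "w") as fh:
        fh.write("mirna\ttranscript\tstart\tscore\tpairing\n")
        for a in alignments:
            fh.write(f"{a.mirna_name}\t{a.transcript_id}\t{a.site_start + 1}"
                     f"\t{a.score:g}\t{a.pairing}\n")
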