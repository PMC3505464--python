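"""Low-level nucleotide string helpers shared across modules.

All internal sequence space is DNA (A/C/G/T); RNA input (U) is
canonicalised to T at ingest and converted back to U only for display
and for secondary-structure work.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def canonical(seq: str) -> str:
    """Uppercase and map U->T so genome matching happens in DNA space."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    return all(c in "ACGT" for c in seq)


# Watson-Crick plus G:U wobble, in RNA space (T accepted as U).
_PAIRABLE = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),
}


def can_pair(a: str, b: str) -> bool:
    """True if bases a and b can form a Watson-Crick or G:U pair."""
    a = "U" if a in "TU" else a
    b = "U" if b in "TU" else b
    return (a, b) in _PAIRABLE


def is_watson_crick(a: str, b: str) -> bool:
    a = "U" if a in "TU" else a
    b = "U" if b in "TU" else b
    return (a, b) in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def is_wobble(a: str, b: str) -> bool:
    a = "U" if a in "TU" else a
    b = "U" if b in "TU" else b
    return (a, b) in {("G", "U"), ("U", "G")}
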