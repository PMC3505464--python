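"""Independent brute-force oracles shared by the test suite.

These deliberately re-derive expected results with explicit, naive
arithmetic — no code shared with the implementation paths they check.
"""

import numpy as np

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def _column_penalty(m: str, t: str) -> float:
    if (m, t) in _WC:
        return 0.0
    if (m, t) in _GU:
        return 0.5
    return 1.0


def target_scan_oracle(mirna: str, transcript: str,
                       max_score: float) -> dict[tuple[int, int], float]:
    """Best score per candidate site interval by explicit enumeration
    of every window and every single-gap placement."""
    L = len(mirna)
    found: dict[tuple[int, int], float] = {}

    def keep(key, sc):
        found[key] = min(found.get(key, np.inf), sc)

    for s in range(len(transcript) + 1):
        if s + L <= len(transcript):
            win = transcript[s:s + L][::-1]
            keep((s, s + L), sum(_column_penalty(m, t)
                                 for m, t in zip(mirna, win)))
        if s + L + 1 <= len(transcript):  # bulged transcript base
            win = transcript[s:s + L + 1][::-1]
            for g in range(1, L):
                sc = 2.0
                sc += sum(_column_penalty(m, t)
                          for m, t in zip(mirna[:g], win[:g]))
                sc += sum(_column_penalty(m, t)
                          for m, t in zip(mirna[g:], win[g + 1:]))
                keep((s, s + L + 1), sc)
        if s + L - 1 <= len(transcript):  # skipped miRNA base
            win = transcript[s:s + L - 1][::-1]
            for g in range(1, L - 1):
                sc = 2.0
                sc += sum(_column_penalty(m, t)
                          for m, t in zip(mirna[:g], win[:g]))
                sc += sum(_column_penalty(m, t)
                          for m, t in zip(mirna[g + 1:], win[g:]))
                keep((s, s + L - 1), sc)
    return {k: v for k, v in found.items() if v <= max_score}
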