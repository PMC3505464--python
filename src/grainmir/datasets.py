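"""Bundled reference tables from a published miRNA survey of indica
rice grain filling, used as worked-example inputs.

``load_de_mirnas`` — the 18 miRNAs differentially expressed across the
milk-ripe (G1), soft-dough (G2) and hard-dough (G3) stages: chip stage
means, printed consecutive-stage fold changes and t-test p-values.

``load_novel_candidates`` — the 11 novel miRNA candidates (sequence,
length, sequencing abundance, chromosome, genomic context).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("grainmir").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_de_mirnas() -> pd.DataFrame:
    return _read("grain_filling_de_mirnas.tsv")


def load_novel_candidates() -> pd.DataFrame:
    return _read("novel_mirna_candidates.tsv")
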