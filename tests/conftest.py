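import numpy as np
import pytest

from grainmir import pipeline, simulate
from grainmir._seq import canonical, revcomp


def random_rna(rng, n):
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=n)])


@pytest.fixture(scope="session")
def tiny_fixture(tmp_path_factory):
    """One tiny synthetic input set shared across the session."""
    outdir = tmp_path_factory.mktemp("fixture") / "tiny"
    config = pipeline.make_fixture(outdir, seed=1, scale="tiny")
    return outdir, config


@pytest.fixture(scope="session")
def tiny_run(tiny_fixture):
    """The tiny fixture run end-to-end once."""
    outdir, config = tiny_fixture
    report = pipeline.run(config, outdir)
    return outdir, config, report


@pytest.fixture()
def perfect_hairpin():
    """A planted hairpin whose star arm is the exact reverse complement
    of the mature arm."""
    rng = np.random.default_rng(11)
    return simulate.random_hairpin(rng, "hp1", "chr1", 200,
                                   mature_len=21, loop_len=8)


@pytest.fixture()
def small_catalog():
    """A two-precursor catalog with mature and star records."""
    from grainmir.annotate import Catalog, MatureMiRNARecord

    rng = np.random.default_rng(5)
    entries = []
    precursors = {}
    for i in range(2):
        mature = canonical(random_rna(rng, 21))
        loop = canonical(random_rna(rng, 8))
        star = revcomp(mature)
        pre = mature + loop + star
        pid = f"MIR{i + 1}"
        precursors[pid] = pre
        entries.append(MatureMiRNARecord(f"osa-miR{i + 1}", mature, pid, 0, "5p"))
        entries.append(MatureMiRNARecord(f"osa-miR{i + 1}*", star, pid,
                                         len(mature) + len(loop), "3p"))
    return Catalog(entries, precursors)
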