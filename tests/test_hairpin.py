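"""Hairpin discovery: window excision, star location, duplex scoring,
candidate calling."""

import numpy as np
import pytest

from grainmir import hairpin, simulate
from grainmir._seq import revcomp, to_rna
from grainmir.fold import SecondaryStructure, fold
from grainmir.hairpin import DuplexStats, call_candidate, duplex_stats, find_star
from grainmir.mapping import GenomeHit
from grainmir.preprocess import SmallRead


def _genome(chrom_len=2_000, seed=0):
    rng = np.random.default_rng(seed)
    return {"chr1": "".join(np.array(list("ACGT"))[rng.integers(0, 4,
                                                                chrom_len)])}


class TestExciseWindows:
    def test_mid_chromosome_gives_26_windows(self):
        genome = _genome()
        hit = GenomeHit("r1", "chr1", 1_000, 1_021, "+")
        wins = hairpin.excise_windows(hit, genome)
        assert len(wins) == 26

    def test_near_start_windows_clipped(self):
        genome = _genome()
        hit = GenomeHit("r1", "chr1", 30, 51, "+")
        wins = hairpin.excise_windows(hit, genome)
        assert all(w.start >= 0 and w.end <= 2_000 for w in wins)

    def test_minus_strand_read_in_sense(self):
        genome = _genome()
        hit = GenomeHit("r1", "chr1", 1_000, 1_021, "-")
        read_sense = revcomp(genome["chr1"][1_000:1_021])
        for w in hairpin.excise_windows(hit, genome):
            sub = w.seq[w.read_offset:w.read_offset + 21]
            assert sub == to_rna(read_sense)

    def test_out_of_bounds_hit_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            hairpin.excise_windows(GenomeHit("r", "chr1", 1_990, 2_011, "+"),
                                   _genome())

    def test_genomic_coordinate_roundtrip(self):
        genome = _genome()
        for strand in "+-":
            hit = GenomeHit("r1", "chr1", 1_000, 1_021, strand)
            w = hairpin.excise_windows(hit, genome)[0]
            lo, hi = w.to_genomic(w.read_offset, w.read_offset + 21)
            assert (lo, hi) == (1_000, 1_021)


class TestFindStar:
    def test_perfect_hairpin_star_geometry(self):
        """21-nt mature on the 5p arm pairs a 3p star offset by the
        2-nt 3' overhang."""
        rng = np.random.default_rng(1)
        mature = "".join(np.array(list("ACGU"))[rng.integers(0, 4, 21)])
        pre = mature + "AACAACCA" + to_rna(revcomp(mature))
        s = fold(pre)
        star, reason = find_star(s, (0, 21))
        assert reason == "ok"
        lo, hi = star
        assert pre[lo:hi] == to_rna(revcomp(mature))[2:]

    def test_unpaired_mature_gives_none(self):
        # poly-A mature cannot pair; close with an unrelated stem
        pre = "A" * 21 + "GGGGGGGG" + "UUUU" + "CCCCCCCC"
        s = fold(pre)
        star, reason = find_star(s, (0, 21))
        assert star is None and reason == "unpaired"

    def test_loop_spanning_mature_rejected(self):
        rng = np.random.default_rng(2)
        mature = "".join(np.array(list("ACGU"))[rng.integers(0, 4, 21)])
        pre = mature + "AACAACCA" + to_rna(revcomp(mature))
        s = fold(pre)
        star, reason = find_star(s, (15, 36))  # straddles the loop
        assert star is None and reason == "loop_spanning"

    def test_planted_hairpin_star_recovered(self, perfect_hairpin):
        """Truth comparison against the simulator's planted star arm."""
        hp = perfect_hairpin
        s = fold(hp.precursor_rna)
        ms = hp.mature_offset
        star, reason = find_star(s, (ms, ms + len(hp.mature_seq)))
        assert reason == "ok"
        lo, hi = star
        assert hp.precursor_rna[lo:hi] in hp.star_seq


class TestDuplexStats:
    def _structure(self, db, seq=None):
        return SecondaryStructure(seq or "A" * len(db), db, db.count("("))

    def test_perfect_duplex(self):
        db = "((((((((((....))))))))))"
        s = self._structure(db)
        stats = duplex_stats(s, (0, 10), (14, 24))
        assert (stats.mismatches, stats.bulges) == (0, 0)

    def test_symmetric_internal_loop_is_mismatch(self):
        db = "((((.((((....)))).))))"
        s = self._structure(db)
        stats = duplex_stats(s, (0, 9), (13, 22))
        assert (stats.mismatches, stats.bulges) == (1, 0)

    def test_one_sided_insertion_is_bulge(self):
        db = "((((..((((....))))))))"
        s = self._structure(db)
        stats = duplex_stats(s, (0, 10), (14, 22))
        assert (stats.mismatches, stats.bulges) == (0, 1)

    def test_overlapping_intervals_rejected(self):
        db = "((((((((((....))))))))))"
        with pytest.raises(ValueError, match="overlap"):
            duplex_stats(self._structure(db), (0, 12), (10, 24))


class TestCallCandidate:
    @pytest.mark.parametrize("mm,bulges,star_reads,known,verdict", [
        (2, 1, 3, False, "accepted"),
        (6, 3, 1, False, "accepted"),
        (7, 0, 1, False, "rejected:mismatches"),
        (0, 4, 1, False, "rejected:bulges"),
        (0, 0, 0, False, "rejected:no_star"),
        (0, 0, 5, True, "rejected:known"),
    ])
    def test_verdicts(self, mm, bulges, star_reads, known, verdict):
        stats = DuplexStats(mm, bulges, (0, 21), (30, 51))
        assert call_candidate(stats, star_reads, known) == verdict

    def test_acceptance_monotone_in_thresholds(self):
        """Tightening the mismatch/bulge caps never accepts a
        candidate rejected at looser caps."""
        for mm in range(9):
            for bulges in range(6):
                stats = DuplexStats(mm, bulges, (0, 21), (30, 51))
                accepted = [call_candidate(stats, 1, False, m, b) == "accepted"
                            for m, b in [(4, 2), (6, 3), (8, 5)]]
                assert accepted == sorted(accepted)


class TestDiscovery:
    def test_planted_hairpin_recovered_end_to_end(self):
        rng = np.random.default_rng(3)
        hp = simulate.random_hairpin(rng, "hp1", "chr1", 800, mature_len=21)
        genome, truth = simulate.generate_genome(1, 2_000, [hp], seed=3)
        from grainmir import mapping
        mature = truth.iloc[0].mature_seq
        star = truth.iloc[0].star_seq
        reads = [SmallRead(mature, 10), SmallRead(star, 2)]
        index = mapping.build_index(genome)
        hit_map, _ = mapping.map_reads(reads, index)
        cands = hairpin.discover(reads, hit_map, genome)
        assert len(cands) == 1
        c = cands[0]
        assert c.verdict == "accepted"
        assert c.start <= truth.iloc[0].start and c.end >= 821
        assert c.star_reads >= 1 and c.mature_reads >= 10

    def test_no_candidates_without_star_reads(self):
        rng = np.random.default_rng(4)
        hp = simulate.random_hairpin(rng, "hp1", "chr1", 800, mature_len=21)
        genome, truth = simulate.generate_genome(1, 2_000, [hp], seed=4)
        from grainmir import mapping
        reads = [SmallRead(truth.iloc[0].mature_seq, 10)]
        index = mapping.build_index(genome)
        hit_map, _ = mapping.map_reads(reads, index)
        assert hairpin.discover(reads, hit_map, genome) == []

    def test_known_reads_do_not_seed_discovery(self):
        rng = np.random.default_rng(5)
        hp = simulate.random_hairpin(rng, "hp1", "chr1", 800, mature_len=21)
        genome, truth = simulate.generate_genome(1, 2_000, [hp], seed=5)
        from grainmir import mapping
        mature, star = truth.iloc[0].mature_seq, truth.iloc[0].star_seq
        reads = [SmallRead(mature, 10), SmallRead(star, 2)]
        index = mapping.build_index(genome)
        hit_map, _ = mapping.map_reads(reads, index)
        cands = hairpin.discover(reads, hit_map, genome,
                                 known_sequences={mature, star})
        assert cands == []
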