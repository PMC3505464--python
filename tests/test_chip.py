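"""Chip expression analysis: normalization, detection, fold changes,
classification, Venn partitioning, ddCt."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from grainmir import chip, simulate


def _table(chips):
    """chips: {(stage, rep): [signals]} -> long signal table."""
    rows = []
    for (stage, rep), signals in chips.items():
        for i, s in enumerate(signals):
            rows.append({"probe_id": f"p{i}", "stage": stage,
                         "replicate": rep, "signal": s})
    return pd.DataFrame(rows)


class TestNormalize:
    def test_median_scaling_against_reference(self):
        sig = _table({("G1", 1): [50, 100, 150], ("G1", 2): [100, 200, 300]})
        bg = pd.DataFrame([
            {"stage": "G1", "replicate": 1, "bg_mean": 0.0, "bg_sd": 1.0},
            {"stage": "G1", "replicate": 2, "bg_mean": 0.0, "bg_sd": 1.0}])
        out = chip.normalize(sig, bg)
        chip2 = out[out["replicate"] == 2]["signal"].tolist()
        assert chip2 == [50.0, 100.0, 150.0]  # scaled by 100/200

    def test_identical_chips_identity(self):
        sig = _table({("G1", 1): [50, 100, 150], ("G1", 2): [50, 100, 150]})
        bg = pd.DataFrame([
            {"stage": "G1", "replicate": 1, "bg_mean": 0.0, "bg_sd": 1.0},
            {"stage": "G1", "replicate": 2, "bg_mean": 0.0, "bg_sd": 1.0}])
        out = chip.normalize(sig, bg)
        assert out["signal"].tolist() == [50.0, 100.0, 150.0] * 2

    def test_below_background_floored_at_zero(self):
        sig = _table({("G1", 1): [10, 100, 150]})
        bg = pd.DataFrame([{"stage": "G1", "replicate": 1,
                            "bg_mean": 30.0, "bg_sd": 1.0}])
        out = chip.normalize(sig, bg)
        assert out["signal"].iloc[0] == 0.0

    def test_missing_background_is_error(self):
        sig = _table({("G1", 1): [10], ("G2", 1): [10]})
        bg = pd.DataFrame([{"stage": "G1", "replicate": 1,
                            "bg_mean": 0.0, "bg_sd": 1.0}])
        with pytest.raises(ValueError, match="background"):
            chip.normalize(sig, bg)


class TestDetect:
    def test_below_floor(self):
        call = chip.detect("p", "G1", np.array([31.0, 31.0, 31.0]), 5.0)
        assert not call.detected and "below_floor" in call.reasons

    def test_cv_fail(self):
        x = np.array([200.0, 500.0, 800.0])  # cv = 0.6
        call = chip.detect("p", "G1", x, 5.0)
        assert not call.detected and "cv_fail" in call.reasons

    def test_all_gates_pass(self):
        x = np.array([480.0, 500.0, 520.0])
        call = chip.detect("p", "G1", x, 50.0)
        assert call.detected and call.reasons == ()

    def test_below_3sd(self):
        x = np.array([120.0, 118.0, 122.0])
        call = chip.detect("p", "G1", x, 50.0)
        assert not call.detected and "below_3sd" in call.reasons

    def test_monotone_in_mean(self):
        """At fixed cv and background, raising the mean never turns a
        detected probe undetected."""
        prev = False
        for mean in [10, 40, 160, 640, 2560]:
            x = mean * np.array([0.9, 1.0, 1.1])
            detected = chip.detect("p", "G1", x, 10.0).detected
            assert detected >= prev
            prev = detected


class TestFoldChange:
    @pytest.mark.parametrize("a,b,expected", [
        (53, 293, 5.53), (349, 1140, 3.27), (56, 53, 0.95),
        (251, 69, 0.27), (7.0, 7.0, 1.00),
    ])
    def test_published_and_identity_values(self, a, b, expected):
        assert chip.fold_change(a, b) == expected

    def test_zero_denominator(self):
        with pytest.raises(ValueError, match="zero_denominator"):
            chip.fold_change(0, 100)

    def test_reciprocity_within_rounding(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b = rng.uniform(10, 5_000, 2)
            f_ab, f_ba = chip.fold_change(a, b), chip.fold_change(b, a)
            # each factor is exact to +/-0.005, so the product deviates
            # by at most 0.005*(f_ab + f_ba) plus a negligible cross term
            assert abs(f_ab * f_ba - 1) <= 0.005 * (f_ab + f_ba) + 1e-4

    def test_half_up_rounding(self):
        assert chip.round_half_up(0.125, 2) == 0.13
        assert chip.round_half_up(2.675, 2) == 2.68


class TestDifferentialTest:
    def test_identical_groups_p_one(self):
        assert chip.differential_test([5, 5, 5], [5, 5, 5]) == 1.0

    def test_matches_independent_t_formula(self):
        """Pooled-variance two-sample t computed by hand."""
        a, b = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        expected = 2 * sps.t.sf(abs(t), 4)
        assert chip.differential_test(a, b, log2=False) == \
            pytest.approx(expected)

    def test_insufficient_replicates(self):
        with pytest.raises(ValueError, match="insufficient_replicates"):
            chip.differential_test([1.0], [2.0, 3.0])


class TestClassifyRegulation:
    @pytest.mark.parametrize("means,expected", [
        ((251, 69, 38), "down"),
        ((100, 100, 100), "unchanged"),
        ((50, 120, 260), "up"),
        ((30, 40, 50), "low_abundance"),
        ((100, 300, 100), "unchanged"),  # conflicting directions
    ])
    def test_classes(self, means, expected):
        assert chip.classify_regulation(means) == expected


class TestStageOverlap:
    def _calls(self, spec):
        rows = []
        for probe, stages in spec.items():
            for s in chip.STAGES:
                rows.append({"probe_id": probe, "stage": s,
                             "detected": s in stages})
        return pd.DataFrame(rows)

    def test_exclusive_region(self):
        venn = chip.stage_overlap(self._calls({"p1": {"G1"}}))
        assert venn["G1"] == 1 and venn["G1&G2&G3"] == 0

    def test_everything_everywhere(self):
        venn = chip.stage_overlap(
            self._calls({f"p{i}": {"G1", "G2", "G3"} for i in range(5)}))
        assert venn["G1&G2&G3"] == 5

    def test_partition_property(self):
        rng = np.random.default_rng(7)
        spec = {}
        for i in range(60):
            stages = {s for s in chip.STAGES if rng.random() < 0.5}
            spec[f"p{i}"] = stages
        venn = chip.stage_overlap(self._calls(spec))
        union = sum(1 for s in spec.values() if s)
        assert sum(venn.values()) == union


class TestDdct:
    @pytest.mark.parametrize("target,ref,expected", [
        ((20.0, 20.0), (15.0, 15.0), 1.0),
        ((19.0, 20.0), (15.0, 15.0), 2.0),
        ((22.0, 20.0), (15.0, 15.0), 0.25),
    ])
    def test_fold_values(self, target, ref, expected):
        assert chip.ddct(target, ref) == pytest.approx(expected)


class TestSimulatedRecovery:
    def test_planted_multiplier_recovered(self):
        """fc_32 of probes simulated at multiplier 5.53 lands within
        +/-5% after background subtraction (no median scaling: every
        probe carries the shift, so chip medians are not comparable)."""
        truths = [simulate.ChipTruth(f"p_{i:03d}", 200.0, (1.0, 1.0, 5.53),
                                     noise_cv=0.08) for i in range(200)]
        signals, background = simulate.simulate_chip(
            truths, replicates=3, background_mean=30.0, background_sd=4.0,
            seed=13)
        sub = signals.merge(background, on=["stage", "replicate"])
        sub["signal"] = (sub["signal"] - sub["bg_mean"]).clip(lower=0)
        de = chip.de_table(sub[["probe_id", "stage", "replicate", "signal"]])
        assert abs(de["fc_32"].mean() - 5.53) / 5.53 < 0.05
        assert (de["regulation"] == "up").all()
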