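"""Control-correction semantics: classification, subtraction, rarefaction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aerosource import decontam, synth
from aerosource.containers import CountTable, Habitat, SampleInfo, ValidationError


def make_table(rows, samples, values):
    return CountTable(pd.DataFrame(values, index=rows, columns=samples))


META2 = [
    SampleInfo("E1", Habitat.DOWNWIND, "L01"),
    SampleInfo("E2", Habitat.UPWIND, "L01"),
    SampleInfo("N1", Habitat.NTC, "control"),
]


class TestRelativeSubtract:
    def test_printed_formula_hand_example(self):
        assert decontam.relative_subtract(50, 1000, 2, 100) == 30.0

    def test_zero_control_count_is_identity(self):
        assert decontam.relative_subtract(50, 1000, 0, 100) == 50.0

    def test_negative_result_clamped(self):
        # 5 - (1000/100)*2 = -15 -> 0
        assert decontam.relative_subtract(5, 1000, 2, 100) == 0.0
        assert decontam.relative_subtract(5, 1000, 2, 100, clamp_negative=False) == -15.0

    def test_zero_control_library_rejected(self):
        with pytest.raises(ValidationError):
            decontam.relative_subtract(5, 100, 1, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10**4), st.integers(1, 10**5),
           st.integers(0, 100), st.integers(0, 100), st.integers(1, 10**3))
    def test_monotone_in_both_counts(self, count_s, lib_s, ntc_a, ntc_b, lib_ntc):
        lo, hi = sorted([ntc_a, ntc_b])
        assert (decontam.relative_subtract(count_s, lib_s, hi, lib_ntc)
                <= decontam.relative_subtract(count_s, lib_s, lo, lib_ntc))
        assert (decontam.relative_subtract(count_s + 1, lib_s, lo, lib_ntc)
                >= decontam.relative_subtract(count_s, lib_s, lo, lib_ntc))

    def test_scale_equivariance(self):
        # doubling sample and control libraries together with control counts
        # leaves corrected proportions unchanged
        a = decontam.relative_subtract(50, 1000, 2, 100) / 1000
        b = decontam.relative_subtract(100, 2000, 4, 200) / 2000
        assert a == pytest.approx(b, abs=1e-12)


class TestClassify:
    def test_similar_read_numbers_go_to_remove(self):
        t = make_table(["O1"], ["E1", "E2", "N1"], [[100, 100, 99]])
        cls = decontam.classify_control_otus(t, META2, Habitat.NTC)
        assert cls.remove == ["O1"] and cls.subtract == []

    def test_far_above_threshold_goes_to_subtract(self):
        # equal library sizes arranged via a filler OTU absent from controls
        t = make_table(["O1", "O2"], ["E1", "E2", "N1"],
                       [[1000, 1000, 2], [0, 0, 998]])
        meta = META2
        cls = decontam.classify_control_otus(t, meta, Habitat.NTC)
        assert "O1" in cls.subtract

    def test_absent_from_controls_untouched(self):
        t = make_table(["O1", "O2"], ["E1", "E2", "N1"], [[5, 7, 0], [1, 1, 3]])
        cls = decontam.classify_control_otus(t, META2, Habitat.NTC)
        assert "O1" not in cls.remove + cls.subtract

    def test_missing_control_habitat_errors(self):
        t = make_table(["O1"], ["E1", "E2"], [[5, 7]])
        with pytest.raises(ValidationError):
            decontam.classify_control_otus(
                t, META2[:2], Habitat.NTC
            )

    def test_inverted_rule_swaps_sets(self):
        t = make_table(["O1"], ["E1", "E2", "N1"], [[100, 100, 99]])
        cfg = decontam.DecontamConfig(invert_rule=True)
        cls = decontam.classify_control_otus(t, META2, Habitat.NTC, cfg)
        assert cls.subtract == ["O1"] and cls.remove == []


class TestApplyCorrection:
    def test_worked_toy_matches_hand_computation(self, toy_counts, toy_meta, toy_expected):
        corrected, report = decontam.apply_correction(toy_counts, toy_meta)
        assert corrected.data.equals(toy_expected.data)
        assert [r["otu_id"] for r in report.removed_otus] == ["O1"]
        assert [r["otu_id"] for r in report.subtracted_otus] == ["O2"]
        assert report.reads_before == {"E1": 1000.0, "E2": 500.0}
        assert report.reads_after == {"E1": 942.0, "E2": 471.0}

    def test_all_zero_controls_drop_columns_only(self):
        t = make_table(["O1", "O2"], ["E1", "E2", "N1"], [[5, 7, 0], [1, 2, 0]])
        corrected, report = decontam.apply_correction(t, META2)
        assert corrected.sample_ids == ["E1", "E2"]
        assert corrected.data.equals(t.data[["E1", "E2"]])
        assert not report.removed_otus and not report.subtracted_otus

    def test_no_controls_at_all_errors(self):
        t = make_table(["O1"], ["E1", "E2"], [[5, 7]])
        with pytest.raises(ValidationError, match="skip"):
            decontam.apply_correction(t, META2[:2])

    def test_never_increases_any_cell(self, small_study):
        table, meta, _ = small_study
        corrected, _ = decontam.apply_correction(table, meta)
        original = table.data.loc[corrected.data.index, corrected.sample_ids]
        # allow +0.5 for half-to-even rounding of real-valued intermediates
        assert (corrected.data.to_numpy() <= original.to_numpy() + 0.5).all()

    def test_recovers_known_contaminants(self, small_cfg):
        removed_hits, genuine_hits = [], []
        for seed in range(5):
            cfg = synth.SynthConfig(**{**small_cfg.__dict__, "seed": seed})
            table, meta, truth = synth.generate_study(cfg)
            _, report = decontam.apply_correction(table, meta)
            removed = {r["otu_id"] for r in report.removed_otus}
            cont = set(truth.contaminant_only_otus())
            removed_hits.append(len(removed & cont) / len(cont))
            genuine = set(truth.genuine_otus())
            genuine_hits.append(len(removed & genuine) / len(genuine))
        assert np.mean(removed_hits) >= 0.9
        assert np.mean(genuine_hits) <= 0.05


class TestRarefy:
    def test_column_at_depth_unchanged(self):
        t = make_table(["A", "B"], ["S1"], [[4], [6]])
        out, dropped = decontam.rarefy(t, 10, seed=1)
        assert out.data["S1"].tolist() == [4, 6] and not dropped

    def test_depth_and_support(self):
        t = make_table(["A", "B", "C"], ["S1"], [[10], [30], [60]])
        out, _ = decontam.rarefy(t, 10, seed=3)
        col = out.data["S1"]
        assert col.sum() == 10 and (col <= [10, 30, 60]).all()

    def test_below_depth_dropped_and_reported(self):
        t = make_table(["A"], ["S1", "S2"], [[5, 50]])
        out, dropped = decontam.rarefy(t, 10, seed=0)
        assert dropped == ["S1"] and out.sample_ids == ["S2"]

    def test_seed_reproducible(self):
        t = make_table(["A", "B", "C"], ["S1", "S2"], [[10, 5], [30, 6], [60, 7]])
        a, _ = decontam.rarefy(t, 12, seed=9)
        b, _ = decontam.rarefy(t, 12, seed=9)
        assert a.data.equals(b.data)

    def test_negative_depth_rejected(self):
        t = make_table(["A"], ["S1"], [[5]])
        with pytest.raises(ValidationError):
            decontam.rarefy(t, -1)

    def test_hypergeometric_mean(self):
        # E[OTU C at depth 10 of (10,30,60)] = 10*60/100 = 6
        t = make_table(["A", "B", "C"], ["S1"], [[10], [30], [60]])
        draws = [decontam.rarefy(t, 10, seed=s)[0].data.at["C", "S1"]
                 for s in range(400)]
        se = np.std(draws, ddof=1) / np.sqrt(len(draws))
        assert np.mean(draws) == pytest.approx(6.0, abs=3 * se + 1e-9)
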