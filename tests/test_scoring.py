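import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edies.scoring import (
    BinGapError,
    BinnedItem,
    CategoricalItem,
    ReferenceTable,
    ScoreTable,
    ScoringError,
    Stratum,
    builtin_printed_fractions,
    builtin_reference,
    builtin_score_table,
    derive_reference,
)

from .conftest import make_record


class TestBuiltinTable:
    def test_score_range(self, table):
        assert table.max_score == 39
        assert table.min_score == 0

    def test_item_inventory(self, table):
        assert [item.name for item in table.items] == [
            "sex", "event", "avpu", "age", "sbp", "hr", "rr", "spo2"]

    @pytest.mark.parametrize(
        "item,value,expected",
        [
            ("sex", "male", 1), ("sex", "female", 0),
            ("event", "disease", 2), ("event", "non_disease", 0),
            ("avpu", "A", 0), ("avpu", "V", 2), ("avpu", "P", 3), ("avpu", "U", 7),
            ("age", 15, 0), ("age", 39, 0), ("age", 40, 1), ("age", 70, 1),
            ("age", 78, 2), ("age", 85, 3), ("age", 93, 4), ("age", 94, 5),
            ("sbp", 20, 11), ("sbp", 21, 11), ("sbp", 22, 10), ("sbp", 130, 0),
            ("sbp", 202, 0), ("sbp", 203, 1), ("sbp", 60, 5), ("sbp", 90.0, 2),
            ("hr", 42, 2), ("hr", 43, 1), ("hr", 87, 0), ("hr", 88, 1),
            ("hr", 120, 1), ("hr", 140, 2), ("hr", 141, 3),
            ("rr", 5, 6), ("rr", 6, 3), ("rr", 7, 3), ("rr", 8, 1),
            ("rr", 13, 1), ("rr", 14, 0), ("rr", 20, 0), ("rr", 21, 1),
            ("rr", 33, 1), ("rr", 34, 2), ("rr", 36, 2),
            ("spo2", 82, 4), ("spo2", 83, 3), ("spo2", 86, 3), ("spo2", 91, 2),
            ("spo2", 96, 1), ("spo2", 97, 0),
        ],
    )
    def test_item_lookups(self, table, item, value, expected):
        assert table.item(item).score(value) == expected

    def test_rr_strict_mode_gap(self):
        strict = builtin_score_table(strict_rr=True)
        assert strict.item("rr").score(33) == 1
        assert strict.item("rr").score(36) == 2
        with pytest.raises(BinGapError):
            strict.item("rr").score(34)
        with pytest.raises(BinGapError):
            strict.item("rr").score(35)

    def test_checksum_is_stable(self):
        assert builtin_score_table().checksum() == builtin_score_table().checksum()


class TestScoreRecord:
    def test_hand_summed_example(self, table):
        record = make_record(sex="male", cause="disease", avpu="A", age=30,
                             sbp=120.0, hr=80.0, rr=16.0, spo2=99.0)
        assert table.score_record(record) == 3  # 1 + 2 + 0*6

    def test_all_minimum_bins(self, table):
        record = make_record(sex="female", cause="non_disease", avpu="A", age=20,
                             sbp=120.0, hr=80.0, rr=16.0, spo2=99.0)
        assert table.score_record(record) == 0

    def test_maximum_record(self, table):
        record = make_record(sex="male", cause="disease", avpu="U", age=95,
                             sbp=20.0, hr=150.0, rr=4.0, spo2=80.0)
        assert table.score_record(record) == 39

    def test_missing_required_field_names_item(self, table):
        record = make_record(sbp=None)
        with pytest.raises(ScoringError, match="sbp"):
            table.score_record(record)

    def test_accepts_mapping_input(self, table):
        fields = dict(sex="male", cause="disease", avpu="A", age=30,
                      sbp=120.0, hr=80.0, rr=16.0, spo2=99.0)
        assert sum(item.score(fields[item.field]) for item in table.items) == 3

    @settings(max_examples=100, deadline=None)
    @given(
        sex=st.sampled_from(["male", "female"]),
        cause=st.sampled_from(["disease", "non_disease"]),
        avpu=st.sampled_from(["A", "V", "P", "U"]),
        age=st.integers(min_value=15, max_value=110),
        sbp=st.floats(min_value=0.1, max_value=300),
        hr=st.floats(min_value=0.1, max_value=250),
        rr=st.floats(min_value=0.1, max_value=60),
        spo2=st.floats(min_value=0.1, max_value=100),
    )
    def test_score_always_in_range(self, table, **fields):
        record = make_record(**fields)
        assert 0 <= table.score_record(record) <= 39

    def test_deterministic(self, table):
        record = make_record()
        assert table.score_record(record) == table.score_record(record)


class TestTableValidation:
    def test_bins_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            BinnedItem(name="x", field="hr", bins=((10, 1), (10, 2)), above=0)

    def test_scores_must_be_non_negative_integers(self):
        item = CategoricalItem(name="x", field="sex", scores={"male": -1, "female": 0})
        with pytest.raises(ValueError, match="non-negative"):
            ScoreTable(items=(item,))

    def test_duplicate_item_names(self):
        item = CategoricalItem(name="x", field="sex", scores={"male": 1, "female": 0})
        with pytest.raises(ValueError, match="duplicate"):
            ScoreTable(items=(item, item))

    def test_round_trip_dict(self, table):
        clone = ScoreTable.from_dict(table.to_dict())
        assert clone == table
        assert clone.checksum() == table.checksum()


class TestBuiltinReference:
    def test_printed_ps_values(self, reference):
        assert reference.ps(0) == 1.00000
        assert reference.ps(1) == 0.99973
        assert reference.ps(14) == 0.95177  # kept as printed
        assert reference.ps(21) == 0.37624
        assert reference.ps(22) == 0.24753
        assert reference.ps(30) == 0.24753  # grouped top bucket

    def test_total_count(self, reference):
        assert reference.total_count == 1_836_577

    def test_non_monotone_flag_and_warning(self, reference):
        assert reference.non_monotone_scores == (14,)
        with pytest.warns(UserWarning, match="non-monotone"):
            builtin_reference()

    def test_fractions_sum_to_one_exactly(self, reference):
        assert sum(s.fraction for s in reference.strata) == pytest.approx(1.0, abs=1e-12)

    def test_printed_fractions_integrity(self, reference):
        printed = builtin_printed_fractions()
        assert sum(printed.values()) == pytest.approx(1.0, abs=1e-3)
        for stratum in reference.strata:
            assert stratum.fraction == pytest.approx(printed[stratum.label], abs=5e-5)

    def test_strata_cover_scores_disjointly(self, reference):
        seen = []
        for stratum in reference.strata:
            seen.extend(stratum.scores)
        assert sorted(seen) == list(range(40))

    def test_expanded_counts_sum(self, reference):
        counts = reference.expanded_counts()
        assert sum(counts.values()) == pytest.approx(1_836_577, abs=1e-6)
        # grouped strata split uniformly over member scores
        assert counts[17] == counts[18] == pytest.approx(1871 / 2)
        assert counts[19] == counts[22] == pytest.approx(1326 / 4)

    def test_round_trip_dict(self, reference):
        clone = ReferenceTable.from_dict(reference.to_dict(), fractions_from_counts=False)
        assert clone.ps(14) == reference.ps(14)
        assert clone.total_count == reference.total_count


@pytest.mark.filterwarnings("ignore:empty survival bucket:UserWarning")
class TestDeriveReference:
    def test_bucket_proportion(self):
        cohort = [(5, "survived")] * 90 + [(5, "died")] * 10
        ref = derive_reference(cohort, strata_spec=[tuple(range(40))])
        assert ref.ps(5) == pytest.approx(0.90)

    def test_single_stratum_fraction(self):
        cohort = [(1, "survived"), (2, "died"), (3, "survived")]
        ref = derive_reference(cohort, strata_spec=[tuple(range(40))])
        assert [s.fraction for s in ref.strata] == [1.0]

    def test_fractions_sum_to_one(self):
        cohort = [(s, "survived") for s in range(20)] * 3
        ref = derive_reference(cohort)
        assert sum(s.fraction for s in ref.strata) == pytest.approx(1.0, abs=1e-9)

    def test_empty_bucket_left_absent_with_warning(self):
        cohort = [(0, "survived")] * 5
        with pytest.warns(UserWarning, match="empty"):
            ref = derive_reference(cohort)
        with pytest.raises(KeyError):
            ref.ps(7)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            derive_reference([])

    def test_parameter_recovery_within_three_binomial_ses(self, rng):
        # simulate a cohort with known survival per score and recover it
        truth = {0: 0.999, 3: 0.95, 8: 0.80, 15: 0.55, 22: 0.25}
        n_per = 50_000
        cohort = []
        for score, ps in truth.items():
            survived = rng.random(n_per) < ps
            cohort.extend((score, "survived" if s else "died") for s in survived)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # unfilled buckets
            ref = derive_reference(cohort)
        for score, ps in truth.items():
            se = np.sqrt(ps * (1 - ps) / n_per)
            assert abs(ref.ps(score) - ps) < 3 * se


class TestReferenceValidation:
    def test_fraction_sum_enforced(self):
        strata = (Stratum("0", (0,), 10, 0.6), Stratum("1", (1,), 10, 0.6))
        with pytest.raises(ValueError, match="sum"):
            ReferenceTable(ps_by_score={0: 1.0, 1: 1.0}, top_ps=0.5,
                           top_ps_min_score=2, strata=strata)

    def test_overlapping_strata_rejected(self):
        strata = (Stratum("a", (0, 1), 10, 0.5), Stratum("b", (1, 2), 10, 0.5))
        with pytest.raises(ValueError, match="overlap"):
            ReferenceTable(ps_by_score={0: 1.0}, top_ps=0.5,
                           top_ps_min_score=3, strata=strata)

    def test_ps_range_enforced(self):
        with pytest.raises(ValueError):
            ReferenceTable(ps_by_score={0: 1.2}, top_ps=0.5, top_ps_min_score=1,
                           strata=(Stratum("0", (0,), 1, 1.0),))
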