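import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietscope.categories import COUNTABLE_CATEGORIES, DETRITUS
from dietscope.data_model import pool_counts
from dietscope.diet_metrics import (
    MetricsConfig,
    frequency_of_occurrence,
    gut_condition_summary,
    percent_number,
    relative_importance,
    relative_niche_width,
    shannon_index,
    summarize_population,
)
from dietscope.errors import EmptyInputError, ValidationError

from .conftest import make_record


class TestFrequencyOfOccurrence:
    def test_detritus_in_11_of_18_guts_is_61_percent(self):
        records = [make_record(f"f{i}", detritus=i < 11, counts={"CLA": 1}) for i in range(18)]
        fo = frequency_of_occurrence(records, DETRITUS)
        assert fo == pytest.approx(100 * 11 / 18)
        assert round(fo) == 61

    def test_ubiquitous_category_is_100(self):
        records = [make_record(f"f{i}", counts={"CLA": 1}) for i in range(5)]
        assert frequency_of_occurrence(records, "CLA") == 100.0

    def test_absent_category_is_0(self):
        records = [make_record(f"f{i}", counts={"CLA": 1}) for i in range(5)]
        assert frequency_of_occurrence(records, "OST") == 0.0

    def test_empty_population_errors(self):
        with pytest.raises(EmptyInputError):
            frequency_of_occurrence([], "CLA")

    def test_nonempty_denominator_monotone_under_added_positive_gut(self):
        records = [
            make_record("a", counts={"CLA": 1}),
            make_record("b", counts={"DIP": 1}),
            make_record("c", counts={}),  # empty gut, excluded from denominator
        ]
        before = frequency_of_occurrence(records, "CLA", "nonempty_guts")
        added = records + [make_record("d", counts={"CLA": 2, "DIP": 1})]
        after = frequency_of_occurrence(added, "CLA", "nonempty_guts")
        assert after >= before


class TestPercentNumber:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"CLA": 90, "DIP": 10}, {"CLA": 90.0, "DIP": 10.0}),
            ({"CLA": 5}, {"CLA": 100.0}),
            ({"CLA": 7, "DIP": 2, "OST": 1}, {"CLA": 70.0, "DIP": 20.0, "OST": 10.0}),
        ],
    )
    def test_hand_normalizations(self, counts, expected):
        m = pool_counts([make_record("a", counts=counts)])
        pn = percent_number(m, "P1")
        for c, v in expected.items():
            assert pn[c] == pytest.approx(v)
        assert sum(pn.values()) == pytest.approx(100.0, abs=1e-9)

    def test_zero_prey_population_all_zero(self):
        m = pool_counts([make_record("a", counts={})])
        assert all(v == 0.0 for v in percent_number(m, "P1").values())


class TestRelativeImportance:
    def test_zero_fo_gives_zero_under_every_variant(self):
        assert relative_importance(0.0, 50.0, variant="hyslop_nv") == 0.0
        assert relative_importance(0.0, 50.0, variant="fo_times_n") == 0.0
        assert relative_importance(0.0, 50.0, variant="raw_count", raw_count=7) == 0.0

    def test_hyslop_formula(self):
        assert relative_importance(50.0, 20.0, pv=30.0, variant="hyslop_nv") == pytest.approx(2500.0)

    def test_fo_times_n_formula(self):
        assert relative_importance(90.0, 90.0, variant="fo_times_n") == pytest.approx(8100.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            relative_importance(-1.0, 10.0)


class TestShannonIndex:
    def test_single_category_is_zero(self):
        assert shannon_index([7]) == 0.0

    def test_uniform_maximum(self):
        for k in (2, 5, 11):
            assert shannon_index([3] * k) == pytest.approx(math.log(k))

    def test_hand_computed_9_1(self):
        expected = -(0.9 * math.log(0.9) + 0.1 * math.log(0.1))
        assert shannon_index([9, 1]) == pytest.approx(expected)
        assert shannon_index([9, 1]) == pytest.approx(0.3251, abs=5e-5)

    def test_all_zero_flagged_zero_not_nan(self):
        assert shannon_index([0, 0, 0]) == 0.0

    def test_base_conversion(self):
        assert shannon_index([1, 1], base=2) == pytest.approx(1.0)

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=2, max_size=8).filter(lambda c: sum(c) > 0))
    def test_invariant_under_permutation_and_bounded(self, counts):
        h = shannon_index(counts)
        assert h == pytest.approx(shannon_index(sorted(counts, reverse=True)))
        nonzero = sum(1 for c in counts if c > 0)
        assert -1e-12 <= h <= math.log(max(nonzero, 1)) + 1e-12

    def test_even_split_into_new_category_increases_h(self):
        # brute-force entropy oracle on small instances
        def entropy(counts):
            total = sum(counts)
            return -sum(c / total * math.log(c / total) for c in counts if c)

        for counts in ([4, 2], [6, 6, 2], [10, 4, 4]):
            split = counts[:-1] + [counts[-1] / 2, counts[-1] / 2]
            assert entropy(split) > entropy(counts)
            assert shannon_index(split) > shannon_index(counts)


class TestRelativeNicheWidth:
    def test_full_diet_is_one(self):
        rec = make_record("a", counts={c: 1 for c in COUNTABLE_CATEGORIES}, detritus=True)
        assert relative_niche_width(rec, 11) == pytest.approx(1.0)

    def test_single_category_is_zero(self):
        assert relative_niche_width(make_record("a", counts={"CLA": 5}), 11) == 0.0

    def test_zero_anchored_formula(self):
        rec = make_record("a", counts={"CLA": 1, "DIP": 2}, detritus=True)  # k = 3
        assert relative_niche_width(rec, 11) == pytest.approx(0.2)

    def test_proportion_variant(self):
        rec = make_record("a", counts={"CLA": 1, "DIP": 2}, detritus=True)
        assert relative_niche_width(rec, 11, variant="proportion") == pytest.approx(3 / 11)

    def test_empty_gut_excluded_signal(self):
        assert relative_niche_width(make_record("a", counts={})) is None

    def test_detritus_counts_as_a_category(self):
        assert relative_niche_width(make_record("a", counts={}, detritus=True), 11) == 0.0


class TestGutCondition:
    def test_study_scale_percentages(self):
        records = (
            [make_record(f"e{i}", counts={}) for i in range(29)]
            + [make_record(f"d{i}", counts={}, detritus=True) for i in range(62)]
            + [make_record(f"p{i}", counts={"CLA": 1}) for i in range(72)]
        )
        cond = gut_condition_summary(records)
        assert cond["n_fish"] == 163
        assert round(cond["empty_percent"], 1) == 17.8
        assert round(cond["detritus_or_unid_only_percent"], 1) == 38.0

    def test_rgl_from_lengths(self):
        cond = gut_condition_summary([make_record("a", sl=20.0, gut_length=12.0)])
        assert cond["rgl_by_sex"]["F"].mean == pytest.approx(0.6)

    def test_missing_fields_skipped_with_count(self):
        records = [make_record("a"), make_record("b", gut_length=None, fullness=None)]
        cond = gut_condition_summary(records)
        assert cond["n_missing_gut_length"] == 1
        assert cond["rgl_by_sex"]["F"].n == 1


def _brute_force_summary(records, k_total=11):
    """Independent recomputation with plain loops (no package calls)."""
    n = len(records)
    pooled = {}
    for r in records:
        for c, v in r.prey_counts.items():
            pooled[c] = pooled.get(c, 0) + v
    total = sum(pooled.values())
    out = {
        "fo": {
            c: 100 * sum(1 for r in records if r.prey_counts.get(c, 0) > 0) / n
            for c in COUNTABLE_CATEGORIES
        },
        "fo_det": 100 * sum(1 for r in records if r.detritus_present) / n,
        "pn": {c: (100 * pooled.get(c, 0) / total if total else 0.0) for c in COUNTABLE_CATEGORIES},
        "empty": 100
        * sum(
            1
            for r in records
            if r.total_prey == 0 and not r.detritus_present and not r.unidentifiable_present
        )
        / n,
    }
    if total:
        probs = [v / total for v in pooled.values() if v > 0]
        out["h"] = -sum(p * math.log(p) for p in probs)
    else:
        out["h"] = 0.0
    rnws = []
    for r in records:
        k = sum(1 for v in r.prey_counts.values() if v > 0) + (1 if r.detritus_present else 0)
        if k > 0:
            rnws.append((k - 1) / (k_total - 1))
    out["mean_rnw"] = sum(rnws) / len(rnws) if rnws else None
    out["iri"] = {c: out["pn"][c] * out["fo"][c] for c in COUNTABLE_CATEGORIES}
    return out


class TestSummarize:
    def _random_population(self, rng, pop="P1", n=None):
        n = n or int(rng.integers(3, 21))
        records = []
        for i in range(n):
            kind = rng.random()
            if kind < 0.2:
                counts, det = {}, False
            elif kind < 0.45:
                counts, det = {}, True
            else:
                cats = rng.choice(COUNTABLE_CATEGORIES, size=int(rng.integers(1, 5)), replace=False)
                counts = {c: int(rng.integers(1, 9)) for c in cats}
                det = bool(rng.random() < 0.4)
            records.append(make_record(f"{pop}f{i}", population_id=pop, counts=counts, detritus=det))
        return records

    def test_agrees_with_bruteforce_on_random_populations(self, rng):
        for trial in range(8):
            records = self._random_population(rng, pop=f"P{trial}")
            cfg = MetricsConfig(iri_variant="fo_times_n")
            (summary,) = summarize_population(records, config=cfg)
            oracle = _brute_force_summary(records)
            for c in COUNTABLE_CATEGORIES:
                assert summary.fo[c] == pytest.approx(oracle["fo"][c])
                assert summary.percent_number[c] == pytest.approx(oracle["pn"][c])
                assert summary.iri[c] == pytest.approx(oracle["iri"][c])
            assert summary.fo[DETRITUS] == pytest.approx(oracle["fo_det"])
            assert summary.shannon_h == pytest.approx(oracle["h"])
            assert summary.empty_percent == pytest.approx(oracle["empty"])
            if oracle["mean_rnw"] is None:
                assert summary.mean_rnw is None
            else:
                assert summary.mean_rnw == pytest.approx(oracle["mean_rnw"])

    def test_all_empty_population_degenerate_contract(self):
        records = [make_record(f"f{i}", counts={}) for i in range(4)]
        (summary,) = summarize_population(records)
        assert summary.empty_percent == 100.0
        assert summary.shannon_flagged_zero and summary.shannon_h == 0.0
        assert summary.mean_rnw is None

    def test_identical_populations_identical_summaries(self):
        recs = [
            make_record(f"f{i}", population_id=p, counts={"CLA": 2, "DIP": 1}, detritus=(i % 2 == 0))
            for p in ("PA", "PB")
            for i in range(6)
        ]
        a, b = summarize_population(recs)
        assert a.fo == b.fo and a.iri == b.iri
        assert a.shannon_h == b.shannon_h and a.mean_rnw == b.mean_rnw

    def test_scale_invariance_of_composition_metrics(self):
        base = [
            make_record("a", counts={"CLA": 3, "DIP": 1}),
            make_record("b", counts={"CLA": 1, "OST": 2}, detritus=True),
        ]
        scaled = [
            make_record(r.fish_id + "s", counts={c: 5 * v for c, v in r.prey_counts.items()},
                        detritus=r.detritus_present)
            for r in base
        ]
        (s1,) = summarize_population(base)
        (s2,) = summarize_population(scaled)
        for c in COUNTABLE_CATEGORIES:
            assert s1.percent_number[c] == pytest.approx(s2.percent_number[c])
        assert s1.shannon_h == pytest.approx(s2.shannon_h)
        assert s1.mean_rnw == pytest.approx(s2.mean_rnw)
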