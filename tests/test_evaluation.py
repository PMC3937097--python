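"""Reference standards, recall@k, weighted precision, sign test, sweeps."""

import numpy as np
import pytest
from scipy.stats import binomtest

from oracles import sign_test_bruteforce
from semspaces.corpus_io import FrequencyTable
from semspaces.evaluation import (
    ReferenceStandard,
    ReferenceStandardError,
    evaluate,
    filter_by_frequency,
    frequency_threshold_sweep,
    load_reference_standard,
    recall_at_k,
    sign_test_exact,
    split_dev_eval,
    weighted_precision,
)


class TestReferenceStandard:
    def test_abbreviation_line_queried_in_task_direction(self, tmp_path):
        p = tmp_path / "ref.tsv"
        p.write_text("vzv\tvaricella\tvattkoppor\n", encoding="utf-8")
        ref = load_reference_standard(p, task="abbr2exp")
        assert ref.queries() == {"vzv": {"varicella", "vattkoppor"}}
        back = ref.retask("exp2abbr")
        assert back.queries() == {"varicella": {"vzv"}, "vattkoppor": {"vzv"}}

    def test_synonym_pairs_queried_both_ways(self, tmp_path):
        p = tmp_path / "ref.tsv"
        p.write_text("a\tb\n", encoding="utf-8")
        ref = load_reference_standard(p, task="syn")
        assert ref.queries() == {"a": {"b"}, "b": {"a"}}

    def test_multiword_terms_dropped_and_tuple_pruned(self, tmp_path):
        p = tmp_path / "ref.tsv"
        p.write_text("x\thjärt infarkt\ny\tz\tw w\n", encoding="utf-8")
        ref = load_reference_standard(p, task="syn")
        assert ref.tuples == (("y", "z"),)

    def test_terms_lowercased_to_match_corpus(self, tmp_path):
        p = tmp_path / "ref.tsv"
        p.write_text("EKG\tElektrokardiogram\n", encoding="utf-8")
        ref = load_reference_standard(p, task="abbr2exp")
        assert ref.tuples == (("ekg", "elektrokardiogram"),)

    def test_single_column_line_is_a_parse_error(self, tmp_path):
        p = tmp_path / "ref.tsv"
        p.write_text("lonely\n", encoding="utf-8")
        with pytest.raises(ReferenceStandardError, match=":1"):
            load_reference_standard(p, task="syn")

    def test_synonym_groups_expand_to_all_other_members(self):
        ref = ReferenceStandard(task="syn", tuples=(("a", "b", "c"),))
        assert ref.queries()["a"] == {"b", "c"}


class TestSplit:
    def _ref(self, n):
        return ReferenceStandard(
            task="syn", tuples=tuple((f"a{i}", f"b{i}") for i in range(n)))

    def test_sizes_differ_by_at_most_one(self):
        dev, ev = split_dev_eval(self._ref(7), seed=0)
        assert (len(dev), len(ev)) == (4, 3)

    def test_deterministic_and_disjoint(self):
        ref = self._ref(12)
        d1, e1 = split_dev_eval(ref, seed=5)
        d2, e2 = split_dev_eval(ref, seed=5)
        assert d1.tuples == d2.tuples and e1.tuples == e2.tuples
        assert not set(d1.tuples) & set(e1.tuples)
        assert set(d1.tuples) | set(e1.tuples) == set(ref.tuples)


class TestFrequencyFilter:
    def test_tuple_dropped_when_any_term_below_threshold(self):
        ref = ReferenceStandard(task="syn", tuples=(("a", "b"),))
        table = FrequencyTable({"a": 50, "b": 49})
        assert filter_by_frequency(ref, table, min_count=50).tuples == ()

    def test_tuple_kept_when_all_terms_meet_threshold_in_all_tables(self):
        ref = ReferenceStandard(task="syn", tuples=(("a", "b"),))
        tables = [FrequencyTable({"a": 50, "b": 50}), FrequencyTable({"a": 51, "b": 50})]
        assert filter_by_frequency(ref, tables, min_count=50).tuples == (("a", "b"),)

    def test_threshold_one_keeps_all_occurring_tuples(self):
        ref = ReferenceStandard(task="syn", tuples=(("a", "b"), ("c", "d")))
        table = FrequencyTable({"a": 1, "b": 9, "c": 3})  # d never occurs
        assert filter_by_frequency(ref, table, min_count=1).tuples == (("a", "b"),)

    def test_adding_a_table_never_increases_survivors(self):
        ref = ReferenceStandard(
            task="syn", tuples=tuple((f"a{i}", f"b{i}") for i in range(5)))
        rng = np.random.default_rng(3)
        t1 = FrequencyTable({t: int(rng.integers(0, 100))
                             for tup in ref.tuples for t in tup})
        t2 = FrequencyTable({t: int(rng.integers(0, 100))
                             for tup in ref.tuples for t in tup})
        one = filter_by_frequency(ref, t1, min_count=30)
        both = filter_by_frequency(ref, [t1, t2], min_count=30)
        assert set(both.tuples) <= set(one.tuples)


class TestRecall:
    def test_micro_average_over_query_gold_pairs(self):
        ref = ReferenceStandard(task="abbr2exp", tuples=(("q1", "g1"), ("q2", "g2", "g3")))
        outputs = {"q1": ["g1", "x"], "q2": ["g2", "y"]}
        assert recall_at_k(outputs, ref, k=10) == pytest.approx(2 / 3)

    def test_empty_outputs_give_zero(self):
        ref = ReferenceStandard(task="abbr2exp", tuples=(("q", "g"),))
        assert recall_at_k({"q": []}, ref) == 0.0

    def test_gold_at_rank_zero_gives_one(self):
        ref = ReferenceStandard(task="abbr2exp", tuples=(("q", "g"),))
        assert recall_at_k({"q": ["g"]}, ref) == 1.0

    def test_monotone_in_k(self):
        ref = ReferenceStandard(task="abbr2exp",
                                tuples=(("q1", "g1"), ("q2", "g2"), ("q3", "g3")))
        outputs = {"q1": ["g1"], "q2": ["x", "y", "z", "g2"], "q3": ["x"]}
        values = [recall_at_k(outputs, ref, k=k) for k in range(1, 6)]
        assert values == sorted(values)


class TestWeightedPrecision:
    def test_all_ten_correct_scores_one(self):
        terms = [f"g{i}" for i in range(10)]
        assert weighted_precision(terms, set(terms), j=10) == 1.0

    def test_only_rank_zero_correct(self):
        terms = ["g"] + [f"x{i}" for i in range(9)]
        assert weighted_precision(terms, {"g"}, j=10) == pytest.approx(10 / 55)

    def test_ranks_zero_and_nine_correct(self):
        terms = ["g1"] + [f"x{i}" for i in range(8)] + ["g2"]
        assert weighted_precision(terms, {"g1", "g2"}, j=10) == pytest.approx(11 / 55)

    def test_dynamic_mode_uses_returned_length(self):
        assert weighted_precision(["g", "x"], {"g"}, j=2) == pytest.approx(2 / 3)

    def test_candidates_beyond_j_are_ignored(self):
        terms = [f"x{i}" for i in range(10)] + ["g"]
        assert weighted_precision(terms, {"g"}, j=10) == 0.0

    def test_promoting_a_true_positive_never_decreases_score(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n_gold = int(rng.integers(1, 4))
            ranks = sorted(rng.choice(10, size=n_gold, replace=False))
            terms = [f"g{r}" if r in ranks else f"x{r}" for r in range(10)]
            gold = {f"g{r}" for r in ranks}
            base = weighted_precision(terms, gold, j=10)
            worst = ranks[-1]
            if worst > 0 and terms[worst - 1] not in gold:
                terms[worst - 1], terms[worst] = terms[worst], terms[worst - 1]
                assert weighted_precision(terms, gold, j=10) >= base


class TestSignTest:
    def test_eight_to_zero_discordance(self):
        a = [True] * 8
        b = [False] * 8
        assert sign_test_exact(a, b) == pytest.approx(0.0078125)

    def test_equal_wins_capped_at_one(self):
        a = [True, False, True, False]
        b = [False, True, False, True]
        assert sign_test_exact(a, b) == 1.0

    def test_no_discordant_pairs(self):
        a = b = [True, True, False]
        assert sign_test_exact(a, b) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sign_test_exact([True], [True, False])

    def test_matches_bruteforce_and_scipy_for_small_n(self):
        for n in range(1, 21):
            for k in range(n + 1):
                a = [True] * k + [False] * (n - k)
                b = [False] * k + [True] * (n - k)
                p = sign_test_exact(a, b)
                assert p == pytest.approx(sign_test_bruteforce(k, n))
                assert p == pytest.approx(binomtest(k, n, 0.5).pvalue)


class TestEvaluateAndSweep:
    def test_report_aggregates_recall_and_precision(self, tmp_path):
        ref = ReferenceStandard(task="syn", tuples=(("a", "b"),))
        outputs = {"a": ["b", "x"], "b": ["y", "x"]}
        report = evaluate(outputs, ref, k=10)
        assert report.n_queries == 2
        assert report.recall_at_k == pytest.approx(0.5)
        assert report.mean_weighted_precision == pytest.approx((10 / 55 + 0) / 2)
        report.to_json(tmp_path / "r.json")
        assert (tmp_path / "r.json").exists()

    def test_dynamic_mode_scores_over_returned_length(self):
        ref = ReferenceStandard(task="syn", tuples=(("a", "b"),))
        report = evaluate({"a": ["b"], "b": ["a"]}, ref, k=10, dynamic=True)
        assert report.mean_weighted_precision == pytest.approx(1.0)

    def test_sweep_reports_threshold_query_count_and_recall(self):
        ref = ReferenceStandard(task="syn", tuples=(("a", "b"), ("c", "d")))
        table = FrequencyTable({"a": 10, "b": 10, "c": 2, "d": 2})
        outputs = {"a": ["b"], "b": ["a"], "c": ["x"], "d": ["x"]}
        df = frequency_threshold_sweep(outputs, ref, table, thresholds=[1, 5, 11])
        assert list(df.threshold) == [1, 5, 11]
        assert list(df.n_queries) == [4, 2, 0]
        assert df.recall.iloc[0] == pytest.approx(0.5)
        assert df.recall.iloc[1] == pytest.approx(1.0)
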