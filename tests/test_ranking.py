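"""Challenge ranking schemes and the annotation-quality screen."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fedsim import MetricTable, qc_screen, rank_task1, rank_task2, within_group_rank


def long_table(rows):
    return pd.DataFrame(
        rows, columns=["algorithm", "case", "institution", "region", "metric", "value"]
    )


def build_entries(per_case_values):
    """per_case_values: {(case, institution): {algorithm: (dsc, hd95)}} applied
    to all three regions (keeps hand enumeration small)."""
    rows = []
    for (case, inst), algos in per_case_values.items():
        for algo, (d, h) in algos.items():
            for region in ("WT", "TC", "ET"):
                rows.append([algo, case, inst, region, "DSC", d])
                rows.append([algo, case, inst, region, "HD95", h])
    return long_table(rows)


def min_rank(values, higher_better):
    """Tiny independent ranker used by the brute-force oracles."""
    order = sorted(values, reverse=higher_better)
    return [1 + order.index(v) for v in values]


class TestWithinGroupRank:
    def test_dsc_ties_take_minimum_rank(self):
        np.testing.assert_array_equal(
            within_group_rank([0.9, 0.7, 0.9], higher_better=True), [1, 3, 1]
        )

    def test_hd95_ascending(self):
        np.testing.assert_array_equal(
            within_group_rank([2.0, 5.0], higher_better=False), [1, 2]
        )

    def test_single_value_rank_one(self):
        np.testing.assert_array_equal(within_group_rank([0.3], True), [1])

    def test_non_finite_ranks_last(self):
        np.testing.assert_array_equal(
            within_group_rank([0.5, np.nan, 0.9], higher_better=True), [2, 3, 1]
        )


class TestRankTask1:
    def test_strict_dominance_gives_scores_one_and_two(self):
        entries = build_entries(
            {
                ("c1", "i1"): {"A": (0.9, 1.0), "B": (0.5, 4.0)},
                ("c2", "i1"): {"A": (0.8, 2.0), "B": (0.4, 5.0)},
            }
        )
        table = MetricTable(entries=entries, convergence={"A": 0.9, "B": 0.5})
        result = rank_task1(table)
        assert result.scores == {"A": pytest.approx(1.0), "B": pytest.approx(2.0)}
        assert result.final_ranks == {"A": 1, "B": 2}

    def test_identical_metrics_all_rank_one(self):
        entries = build_entries(
            {("c1", "i1"): {a: (0.7, 3.0) for a in "ABC"}}
        )
        table = MetricTable(entries=entries, convergence={a: 0.5 for a in "ABC"})
        result = rank_task1(table)
        assert set(result.final_ranks.values()) == {1}

    def test_matches_exhaustive_hand_enumeration(self):
        per_case = {
            ("c1", "i1"): {"A": (0.9, 2.0), "B": (0.7, 1.0), "C": (0.9, 3.0)},
            ("c2", "i1"): {"A": (0.5, 5.0), "B": (0.8, 2.0), "C": (0.6, 2.0)},
        }
        convergence = {"A": 0.6, "B": 0.4, "C": 0.6}
        table = MetricTable(entries=build_entries(per_case), convergence=convergence)
        result = rank_task1(table)

        # oracle: enumerate every one of the N*3*3 ranks per algorithm
        algos = ["A", "B", "C"]
        collected = {a: [] for a in algos}
        conv_ranks = min_rank([convergence[a] for a in algos], higher_better=True)
        for case in ("c1", "c2"):
            dscs = [per_case[(case, "i1")][a][0] for a in algos]
            hds = [per_case[(case, "i1")][a][1] for a in algos]
            for _region in range(3):
                for ranks in (min_rank(dscs, True), min_rank(hds, False)):
                    for a, r in zip(algos, ranks):
                        collected[a].append(r)
            for a, r in zip(algos, conv_ranks):
                collected[a].extend([r] * 3)
        expected = {a: np.mean(collected[a]) for a in algos}
        assert result.scores == pytest.approx(expected)

    def test_missing_convergence_rejected(self):
        entries = build_entries({("c1", "i1"): {"A": (0.9, 1.0), "B": (0.5, 2.0)}})
        with pytest.raises(ValueError, match="convergence"):
            rank_task1(MetricTable(entries=entries))


class TestRankTask2:
    def test_single_institution_reduces_to_case_ranking(self):
        per_case = {
            ("c1", "i1"): {"A": (0.9, 1.0), "B": (0.5, 4.0)},
            ("c2", "i1"): {"A": (0.4, 5.0), "B": (0.8, 2.0)},
        }
        result = rank_task2(MetricTable(entries=build_entries(per_case)))
        # mean per-case ranks are equal (each wins one case) -> tie
        assert result.scores["A"] == result.scores["B"]
        assert set(result.final_ranks.values()) == {1}

    def test_institutions_weighted_equally_regardless_of_size(self):
        # A is best on the 1-case institution, worst on the 4-case one;
        # B is the mirror image: equal-institution weighting ties them.
        per_case = {("big" + str(i), "I-big"): {"A": (0.4, 5.0), "B": (0.9, 1.0)} for i in range(4)}
        per_case[("small", "I-small")] = {"A": (0.9, 1.0), "B": (0.4, 5.0)}
        result = rank_task2(MetricTable(entries=build_entries(per_case)))
        assert result.scores["A"] == pytest.approx(result.scores["B"])

    def test_case_order_invariance(self):
        per_case = {
            ("c1", "i1"): {"A": (0.9, 1.0), "B": (0.5, 4.0)},
            ("c2", "i1"): {"A": (0.4, 5.0), "B": (0.8, 2.0)},
            ("c3", "i2"): {"A": (0.7, 2.0), "B": (0.6, 3.0)},
        }
        entries = build_entries(per_case)
        shuffled = entries.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = rank_task2(MetricTable(entries=entries))
        b = rank_task2(MetricTable(entries=shuffled))
        assert a.scores == b.scores

    def test_duplicating_cases_within_institution_invariant(self):
        per_case = {
            ("c1", "i1"): {"A": (0.9, 1.0), "B": (0.5, 4.0)},
            ("c2", "i2"): {"A": (0.4, 5.0), "B": (0.8, 2.0)},
        }
        doubled = dict(per_case)
        doubled[("c1-copy", "i1")] = per_case[("c1", "i1")]
        a = rank_task2(MetricTable(entries=build_entries(per_case)))
        b = rank_task2(MetricTable(entries=build_entries(doubled)))
        assert a.scores == pytest.approx(b.scores)

    def test_institution_with_missing_model_excluded_and_flagged(self):
        per_case = {
            ("c1", "i1"): {"A": (0.9, 1.0), "B": (0.5, 4.0)},
            ("c2", "i2"): {"A": (0.4, 5.0), "B": (0.8, 2.0)},
        }
        entries = build_entries(per_case)
        # model B could not be evaluated at institution i2
        entries.loc[
            (entries["algorithm"] == "B") & (entries["institution"] == "i2"), "value"
        ] = np.nan
        result = rank_task2(MetricTable(entries=entries))
        assert result.excluded_institutions == ("i2",)
        # only i1 contributes: A dominates there
        assert result.final_ranks == {"A": 1, "B": 2}

    def test_matches_brute_force_on_multi_institution_fixture(self):
        per_case = {
            ("c1", "i1"): {"A": (0.9, 2.0), "B": (0.7, 1.0), "C": (0.9, 3.0)},
            ("c2", "i1"): {"A": (0.5, 5.0), "B": (0.8, 2.0), "C": (0.6, 2.0)},
            ("c3", "i2"): {"A": (0.6, 4.0), "B": (0.6, 4.0), "C": (0.7, 1.0)},
        }
        result = rank_task2(MetricTable(entries=build_entries(per_case)))

        algos = ["A", "B", "C"]
        collected = {a: [] for a in algos}
        for inst, cases in (("i1", ["c1", "c2"]), ("i2", ["c3"])):
            for _region in range(3):
                for metric_idx, higher in ((0, True), (1, False)):
                    per_alg = {a: [] for a in algos}
                    for case in cases:
                        vals = [per_case[(case, inst)][a][metric_idx] for a in algos]
                        for a, r in zip(algos, min_rank(vals, higher)):
                            per_alg[a].append(r)
                    means = [np.mean(per_alg[a]) for a in algos]
                    for a, r in zip(algos, min_rank(means, higher_better=False)):
                        collected[a].append(r)
        expected = {a: np.mean(collected[a]) for a in algos}
        assert result.scores == pytest.approx(expected)

    def test_dominated_algorithm_never_improves_incumbents(self):
        per_case = {
            ("c1", "i1"): {"A": (0.9, 1.0), "B": (0.6, 3.0)},
            ("c2", "i2"): {"A": (0.7, 2.0), "B": (0.8, 1.5)},
        }
        base = rank_task2(MetricTable(entries=build_entries(per_case)))
        with_dud = {
            k: {**v, "Z": (0.1, 99.0)} for k, v in per_case.items()
        }
        extended = rank_task2(MetricTable(entries=build_entries(with_dud)))
        for a in ("A", "B"):
            assert extended.scores[a] <= base.scores[a] + 1e-12


class TestQcScreen:
    def test_flag_count_is_ceil_of_quantile(self):
        dscs = {f"c{i}": 0.5 + 0.01 * i for i in range(10)}
        flagged, _ = qc_screen(dscs, quantile=0.2)
        assert len(flagged) == 2
        assert flagged == ["c0", "c1"]

    def test_quantile_one_flags_all(self):
        dscs = {"a": 0.9, "b": 0.1}
        flagged, _ = qc_screen(dscs, quantile=1.0)
        assert sorted(flagged) == ["a", "b"]

    def test_captured_fraction_reported(self):
        dscs = {"bad1": 0.1, "bad2": 0.2, "good1": 0.9, "good2": 0.95, "good3": 0.99}
        flagged, captured = qc_screen(dscs, quantile=0.4, known_errors=["bad1", "bad2"])
        assert sorted(flagged) == ["bad1", "bad2"]
        assert captured == 1.0

    def test_invalid_quantile_rejected(self):
        with pytest.raises(ValueError, match="quantile"):
            qc_screen({"a": 0.5}, quantile=0.0)
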