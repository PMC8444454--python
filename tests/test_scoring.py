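import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phenoscore.scoring import (
    ScoringError,
    compute_test_scores,
    compute_unified_scores,
    normalize_measure,
    score_cohort,
    score_measures,
)
from phenoscore.traitmap import TraitEntry, TraitMap

from conftest import make_records, random_mini_cohort
from _oracles import brute_force_unified


class TestNormalizeMeasure:
    def test_ratio_to_maximum(self):
        np.testing.assert_allclose(
            normalize_measure([2, 4, 8], +1), [0.25, 0.5, 1.0]
        )

    def test_inversion(self):
        np.testing.assert_allclose(
            normalize_measure([2, 4, 8], -1), [0.75, 0.5, 0.0]
        )

    def test_negative_values_score_zero(self):
        np.testing.assert_allclose(
            normalize_measure([-1, 4, 8], +1), [0.0, 0.5, 1.0]
        )

    def test_timeout_scores_one_and_excluded_from_maximum(self):
        # max over non-timeout values is 6, so 3 -> 0.5; the timeout -> 1
        np.testing.assert_allclose(
            normalize_measure([3, 10, 6], +1, timeouts=[False, True, False]),
            [0.5, 1.0, 1.0],
        )

    def test_timeout_policy_deficit_forces_one_after_inversion(self):
        out = normalize_measure([3, 10, 6], -1, timeouts=[False, True, False])
        np.testing.assert_allclose(out, [0.5, 1.0, 0.0])

    def test_timeout_policy_literal_inverts_timeout(self):
        out = normalize_measure(
            [3, 10, 6], -1, timeouts=[False, True, False], timeout_policy="literal"
        )
        np.testing.assert_allclose(out, [0.5, 0.0, 0.0])

    def test_missing_stays_missing(self):
        out = normalize_measure([2, np.nan, 8], +1)
        assert math.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.25, 1.0])

    def test_degenerate_stratum_all_scores_missing(self):
        out = normalize_measure([-1, -2, -3], +1)
        assert np.isnan(out).all()

    def test_all_missing_rejected(self):
        with pytest.raises(ScoringError):
            normalize_measure([np.nan, np.nan], +1)

    @given(
        values=st.lists(
            st.floats(min_value=0.01, max_value=1e5), min_size=2, max_size=12
        ),
        c=st.floats(min_value=1e-3, max_value=1e3),
        direction=st.sampled_from([+1, -1]),
    )
    def test_scale_invariance(self, values, c, direction):
        base = normalize_measure(values, direction)
        scaled = normalize_measure([c * v for v in values], direction)
        np.testing.assert_allclose(scaled, base, atol=1e-9)

    @given(
        values=st.lists(
            st.floats(min_value=-10, max_value=100), min_size=2, max_size=12
        ).filter(lambda v: max(v) > 0),
        direction=st.sampled_from([+1, -1]),
    )
    def test_all_scores_in_unit_interval(self, values, direction):
        out = normalize_measure(values, direction)
        ok = out[~np.isnan(out)]
        assert ((ok >= 0) & (ok <= 1)).all()

    @given(
        values=st.lists(
            st.floats(min_value=0.01, max_value=100), min_size=2, max_size=12
        )
    )
    def test_inversion_is_involution(self, values):
        plus = normalize_measure(values, +1)
        minus = normalize_measure(values, -1)
        np.testing.assert_allclose(1.0 - minus, plus, atol=1e-12)


class TestTestAndUnifiedScores:
    def test_test_score_is_mean_of_trait_measures(self, simple_trait_map):
        records = make_records(
            [
                # time_in_light inverted: 30/60 -> 0.5 -> 0.5... pick values
                {"animal_id": "a1", "test": "light_dark", "measure": "time_in_light", "value": 30},
                {"animal_id": "a2", "test": "light_dark", "measure": "time_in_light", "value": 60},
                {"animal_id": "a1", "test": "light_dark", "measure": "latency_to_light", "value": 10},
                {"animal_id": "a2", "test": "light_dark", "measure": "latency_to_light", "value": 5},
            ]
        )
        ms, _ = score_measures(records, simple_trait_map)
        ts = compute_test_scores(ms)
        a1 = ts[(ts.animal_id == "a1") & (ts.test == "light_dark")]["score"].item()
        # a1: time_in_light 1 - 30/60 = 0.5; latency 10/10 = 1.0 -> mean 0.75
        assert a1 == pytest.approx(0.75)

    def test_single_measure_test_score_is_identity(self, simple_trait_map):
        records = make_records(
            [
                {"animal_id": "a1", "test": "interaction", "measure": "time_following", "value": 2},
                {"animal_id": "a2", "test": "interaction", "measure": "time_following", "value": 8},
            ]
        )
        ms, _ = score_measures(records, simple_trait_map)
        ts = compute_test_scores(ms)
        assert sorted(ts["score"]) == pytest.approx([0.25, 1.0])

    def test_missing_measure_excluded_from_test_mean(self, simple_trait_map):
        records = make_records(
            [
                {"animal_id": "a1", "test": "light_dark", "measure": "time_in_light", "value": 30},
                {"animal_id": "a2", "test": "light_dark", "measure": "time_in_light", "value": 60},
                {"animal_id": "a1", "test": "light_dark", "measure": "latency_to_light", "value": np.nan},
                {"animal_id": "a2", "test": "light_dark", "measure": "latency_to_light", "value": 5},
            ]
        )
        ms, _ = score_measures(records, simple_trait_map)
        ts = compute_test_scores(ms)
        a1 = ts[(ts.animal_id == "a1") & (ts.test == "light_dark")]["score"].item()
        assert a1 == pytest.approx(0.5)  # only time_in_light contributes

    def test_unified_weights_tests_equally_not_measures(self):
        # anxiety probed by test A (5 measures) and test B (1 measure):
        # per-test scores 0.2 and 0.8 must average to 0.5.
        entries = {("B", "m0"): TraitEntry("anxiety", +1)}
        rows = [
            {"animal_id": "a1", "test": "B", "measure": "m0", "value": 8},
            {"animal_id": "a2", "test": "B", "measure": "m0", "value": 10},
        ]
        for m in range(5):
            entries[("A", f"m{m}")] = TraitEntry("anxiety", +1)
            rows += [
                {"animal_id": "a1", "test": "A", "measure": f"m{m}", "value": 2},
                {"animal_id": "a2", "test": "A", "measure": f"m{m}", "value": 10},
            ]
        ss = score_cohort(make_records(rows), TraitMap(entries))
        a1 = ss.unified_scores.set_index("animal_id")["score"]["a1"]
        assert a1 == pytest.approx(0.5)

    def test_single_contributing_test_unified_is_identity(self, simple_trait_map):
        records = make_records(
            [
                {"animal_id": "a1", "test": "interaction", "measure": "time_following", "value": 2},
                {"animal_id": "a2", "test": "interaction", "measure": "time_following", "value": 8},
            ]
        )
        ss = score_cohort(records, simple_trait_map)
        soc = ss.unified_scores[ss.unified_scores.trait == "sociability"]
        assert sorted(soc["score"]) == pytest.approx([0.25, 1.0])

    def test_all_ones_stay_ones(self, simple_trait_map):
        records = make_records(
            [
                {"animal_id": "a1", "test": "light_dark", "measure": "latency_to_light", "value": 7},
                {"animal_id": "a2", "test": "light_dark", "measure": "latency_to_light", "value": 7},
            ]
        )
        ss = score_cohort(records, simple_trait_map)
        assert (ss.unified_scores["score"] == 1.0).all()

    def test_duplicated_measure_does_not_leak_across_tests(self):
        # duplicating a measure inside test A must not change test B's
        # contribution to the unified score
        entries = {
            ("A", "m0"): TraitEntry("anxiety", +1),
            ("B", "m0"): TraitEntry("anxiety", +1),
        }
        rows = [
            {"animal_id": a, "test": t, "measure": "m0", "value": v}
            for a, vals in (("a1", (2, 6)), ("a2", (10, 3)))
            for t, v in zip(("A", "B"), vals)
        ]
        base = score_cohort(make_records(rows), TraitMap(entries))
        entries2 = dict(entries)
        entries2[("A", "m1")] = TraitEntry("anxiety", +1)
        rows2 = rows + [
            {"animal_id": "a1", "test": "A", "measure": "m1", "value": 2},
            {"animal_id": "a2", "test": "A", "measure": "m1", "value": 10},
        ]
        dup = score_cohort(make_records(rows2), TraitMap(entries2))
        b_base = base.test_scores[base.test_scores.test == "B"].set_index("animal_id")["score"]
        b_dup = dup.test_scores[dup.test_scores.test == "B"].set_index("animal_id")["score"]
        pd.testing.assert_series_equal(b_base, b_dup)


class TestScoringValidation:
    def test_unknown_measure_rejected(self, simple_trait_map):
        records = make_records(
            [{"animal_id": "a1", "test": "light_dark", "measure": "nope", "value": 1}]
        )
        with pytest.raises(ScoringError, match="missing from trait map"):
            score_measures(records, simple_trait_map)

    def test_duplicate_record_rejected(self, simple_trait_map):
        records = make_records(
            [
                {"animal_id": "a1", "test": "interaction", "measure": "time_following", "value": 1},
                {"animal_id": "a1", "test": "interaction", "measure": "time_following", "value": 2},
            ]
        )
        with pytest.raises(ScoringError, match="duplicate"):
            score_measures(records, simple_trait_map)

    def test_timeout_on_non_latency_measure_rejected(self, simple_trait_map):
        records = make_records(
            [
                {"animal_id": "a1", "test": "interaction", "measure": "time_following",
                 "value": 1, "is_timeout": True},
                {"animal_id": "a2", "test": "interaction", "measure": "time_following",
                 "value": 2},
            ]
        )
        with pytest.raises(ScoringError, match="non-latency"):
            score_measures(records, simple_trait_map)

    def test_degenerate_stratum_warns_and_blanks(self, simple_trait_map):
        records = make_records(
            [
                {"animal_id": "a1", "test": "interaction", "measure": "time_following", "value": -1},
                {"animal_id": "a2", "test": "interaction", "measure": "time_following", "value": -2},
            ]
        )
        with pytest.warns(UserWarning, match="degenerate"):
            ms, norm = score_measures(records, simple_trait_map)
        assert ms["score"].isna().all()
        assert norm["degenerate"].all()


class TestBruteForceOracle:
    def test_unified_scores_match_explicit_loop_recomputation(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            records, trait_map = random_mini_cohort(rng)
            ss = score_cohort(records, trait_map)
            expected = brute_force_unified(
                records.to_dict("records"), trait_map
            )
            got = ss.unified_scores.set_index(["animal_id", "trait"])["score"]
            for (animal, trait), exp in expected.items():
                g = got.get((animal, trait), math.nan)
                if math.isnan(exp):
                    assert math.isnan(g) or (animal, trait) not in got.index
                else:
                    assert g == pytest.approx(exp, abs=1e-12)
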