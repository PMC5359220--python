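"""Summaries, similarity-structure tables, and human-fixture comparison."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from hybridcat import (
    EXPERIMENT1,
    EXPERIMENT3,
    MemoryParams,
    RunConfig,
    aggregate_runs,
    compare_to_fixture,
    run_condition,
    summarize,
    weighted_similarity_table,
)


def make_trials(rows):
    base = dict(
        run_id=0, block=1, trial_index=0, stimulus_id="s", compliant=True,
        similarity="high", selected_route="rule", route="rule", label="member",
        correct=True, latency_ms=1000.0, clock_s=0.0,
    )
    records = []
    for i, row in enumerate(rows):
        r = dict(base)
        r.update(row, trial_index=i)
        records.append(r)
    return pd.DataFrame.from_records(records)


class TestSummarize:
    def test_uniform_correct_trials(self):
        rows = [
            {"similarity": sim, "block": b}
            for sim in ("high", "low")
            for b in (1, 2, 3, 4)
            for _ in range(3)
        ]
        s = summarize(make_trials(rows))
        assert s.mean_errors == 0
        assert s.rt_effect_ms == pytest.approx(0.0)

    def test_constructed_hundred_ms_effect(self):
        rows = [{"similarity": "high", "latency_ms": 900.0} for _ in range(5)] + [
            {"similarity": "low", "latency_ms": 1000.0} for _ in range(5)
        ]
        s = summarize(make_trials(rows))
        assert s.rt_effect_ms == pytest.approx(100.0)

    def test_incorrect_trials_excluded_from_rt(self):
        rows = [
            {"similarity": "high", "latency_ms": 900.0},
            {"similarity": "high", "latency_ms": 100.0, "correct": False},
            {"similarity": "low", "latency_ms": 1000.0},
            {"similarity": "low", "latency_ms": 9000.0, "correct": False},
        ]
        s = summarize(make_trials(rows))
        assert s.rt_effect_ms == pytest.approx(100.0)
        assert s.mean_errors == 2

    def test_empty_rt_cell_is_nan_not_imputed(self):
        rows = [
            {"similarity": "high", "latency_ms": 900.0},
            {"similarity": "low", "correct": False},
        ]
        s = summarize(make_trials(rows))
        assert np.isnan(s.rt_effect_ms)

    def test_permutation_invariance(self):
        rows = [
            {"similarity": sim, "latency_ms": 500.0 + 100 * i, "correct": i % 3 > 0}
            for i, sim in enumerate(["high", "low"] * 10)
        ]
        df = make_trials(rows)
        shuffled = df.sample(frac=1.0, random_state=0)
        a, b = summarize(df), summarize(shuffled)
        assert a.mean_errors == b.mean_errors
        assert a.rt_effect_ms == pytest.approx(b.rt_effect_ms)

    def test_multi_run_frame_rejected(self):
        df = make_trials([{}, {}])
        df.loc[1, "run_id"] = 1
        with pytest.raises(ValueError):
            summarize(df)

    def test_aggregate_counts_defined_effects(self):
        df0 = make_trials([{"similarity": "high"}, {"similarity": "low"}])
        df1 = make_trials([{"similarity": "high"}, {"similarity": "low", "correct": False}])
        df1["run_id"] = 1
        res = aggregate_runs(pd.concat([df0, df1], ignore_index=True))
        assert res.n_runs == 2
        assert res.rt_effect_n == 1


class TestNoiseFreeShareOnePattern:
    def test_per_condition_rates(self, default_design):
        cfg = RunConfig(
            mode="unsupervised", target_share=1.0, n_runs=2,
            memory=MemoryParams(s_act=0.0), seed=17,
        )
        res = run_condition(cfg, default_design)
        assert res.per_condition_error_rate == {
            "compliant-high": 0.0,
            "compliant-low": 1.0,
            "non-compliant-high": 1.0,
            "non-compliant-low": 0.0,
        }


class TestWeightedSimilarity:
    def test_equal_weights_training_reference_orders_by_similarity(self, default_design):
        table = weighted_similarity_table(default_design, 1.0, 1.0, "training")
        assert table["compliant-high"] > table["compliant-low"]
        assert table["non-compliant-high"] > table["non-compliant-low"]

    def test_heavy_rule_weight_erases_similarity_difference(self, default_design):
        table = weighted_similarity_table(default_design, 10.0, 1.0, "training")
        assert abs(table["compliant-high"] - table["compliant-low"]) < 0.1
        assert abs(table["non-compliant-high"] - table["non-compliant-low"]) < 0.1
        # ... while compliance still separates the conditions.
        assert table["compliant-low"] - table["non-compliant-high"] > 0.5

    @pytest.mark.parametrize("rule_w, irr_w", [(1.0, 1.0), (2.0, 1.0), (10.0, 1.0)])
    def test_test_reference_shows_no_similarity_difference(self, default_design, rule_w, irr_w):
        table = weighted_similarity_table(default_design, rule_w, irr_w, "test")
        assert abs(table["compliant-high"] - table["compliant-low"]) < 0.05
        assert abs(table["non-compliant-high"] - table["non-compliant-low"]) < 0.05

    def test_normalisation(self, default_design):
        table = weighted_similarity_table(default_design, 2.0, 1.0, "training")
        assert table.min() == pytest.approx(0.0)
        assert table.max() == pytest.approx(1.0)
        assert ((table >= 0) & (table <= 1)).all()

    def test_label_swap_invariance_with_test_reference(self, default_design):
        """Swapping the high/low labels leaves the test-reference table
        unchanged: the test set itself is similarity-balanced."""
        d = default_design
        swapped_test = [
            dataclasses.replace(s, similarity={"high": "low", "low": "high"}[s.similarity])
            for s in d.test
        ]
        swapped = type(d)(d.spec, d.rule, d.training, swapped_test)
        a = weighted_similarity_table(d, 1.0, 1.0, "test")
        b = weighted_similarity_table(swapped, 1.0, 1.0, "test")
        assert a["compliant-high"] == pytest.approx(b["compliant-low"], abs=1e-9)
        assert a["non-compliant-high"] == pytest.approx(b["non-compliant-low"], abs=1e-9)

    def test_zero_weights_rejected(self, default_design):
        with pytest.raises(ValueError):
            weighted_similarity_table(default_design, 0.0, 0.0)


class TestFixtureComparison:
    def _result(self, errors, rt):
        from hybridcat.analysis import ConditionResult

        return ConditionResult(
            mode="unsupervised", target_share=0.1, n_runs=50, mean_errors=errors,
            rt_effect_ms=rt, rt_effect_n=50, per_condition_error_rate={},
            per_block_rt=pd.DataFrame(), exemplar_share=0.1,
            per_block_share=pd.Series(dtype=float), per_run=pd.DataFrame(),
        )

    def test_exact_match_gives_zero_deltas(self):
        report = compare_to_fixture(self._result(4.0, 114.0), EXPERIMENT3)
        assert report["rt_effect_delta_ms"] == 0.0
        assert report["errors_delta"] == 0.0
        assert report["rt_effect_within"] and report["errors_within"]

    def test_signed_rt_delta(self):
        report = compare_to_fixture(self._result(7.0, 46.0), EXPERIMENT1)
        assert report["rt_effect_delta_ms"] == pytest.approx(-16.0)
        assert not report["rt_effect_within"]
        assert report["errors_within"]  # 7/96 sits inside the 5-9% band
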