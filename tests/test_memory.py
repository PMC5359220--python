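"""Declarative-memory primitives: activation, retrieval, latency."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridcat import (
    Chunk,
    DeclarativeMemory,
    MemoryParams,
    activation,
    base_level,
    partial_match,
    retrieval_latency,
    retrieval_probability,
)
from hybridcat.memory import MemoryError_


def exemplar(features, refs, name="ex"):
    return Chunk(name, "exemplar", tuple(features), references=list(refs))


class TestBaseLevel:
    def test_single_reference_one_second(self):
        assert base_level(exemplar("a", [0.0]), now=1.0, d=0.5) == pytest.approx(0.0)

    def test_two_references(self):
        # (1)^-0.5 + (4)^-0.5 = 1.5
        c = exemplar("a", [0.0, 3.0])
        assert base_level(c, now=4.0, d=0.5) == pytest.approx(math.log(1.5))

    def test_decays_with_elapsed_time(self):
        c = exemplar("a", [0.0])
        assert base_level(c, 100.0) < base_level(c, 1.0)

    def test_reference_at_or_after_now_raises(self):
        with pytest.raises(MemoryError_):
            base_level(exemplar("a", [5.0]), now=5.0)

    @given(
        refs=st.lists(st.floats(0.0, 99.0), min_size=1, max_size=10),
        extra=st.floats(0.0, 99.0),
        dt=st.floats(0.5, 1000.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotonicity(self, refs, extra, dt):
        """An added reference never lowers the base level at fixed time;
        more elapsed time never raises it."""
        refs = sorted(refs)
        c = exemplar("a", refs)
        b0 = base_level(c, 100.0)
        c_more = exemplar("a", sorted(refs + [extra]))
        assert base_level(c_more, 100.0) >= b0
        assert base_level(c, 100.0 + dt) <= b0


class TestPartialMatch:
    params = MemoryParams(s_act=0.0)

    @pytest.mark.parametrize(
        "n_match, expected", [(4, 2.0), (6, 6.0), (0, -6.0)]
    )
    def test_defaults(self, n_match, expected):
        chunk = exemplar(["m"] * n_match + ["x"] * (6 - n_match), [0.0])
        probe = ["m"] * n_match + ["y"] * (6 - n_match)
        assert partial_match(probe, chunk, self.params) == pytest.approx(expected)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(MemoryError_):
            partial_match(["a"] * 5, exemplar(["a"] * 6, [0.0]), self.params)

    def test_rule_chunk_rejected(self):
        rule_chunk = Chunk("rule", "rule", object(), references=[0.0])
        with pytest.raises(MemoryError_):
            partial_match(["a"] * 6, rule_chunk, self.params)


class TestActivation:
    def test_noise_free_composition(self):
        """Base level ln(1.5) plus a 4/6 partial match of +2."""
        params = MemoryParams(s_act=0.0)
        chunk = exemplar(list("abcdxy"), [0.0, 3.0])
        a = activation(chunk, list("abcdef"), now=4.0, params=params)
        assert a == pytest.approx(math.log(1.5) + 2.0, abs=1e-9)

    def test_rule_chunk_without_probe_is_base_level_only(self):
        params = MemoryParams(s_act=0.0)
        rule_chunk = Chunk("rule", "rule", object(), references=[0.0])
        assert activation(rule_chunk, None, 1.0, params) == pytest.approx(0.0)

    def test_probe_iff_exemplar_enforced(self):
        params = MemoryParams(s_act=0.0)
        with pytest.raises(MemoryError_):
            activation(exemplar("abcdef", [0.0]), None, 1.0, params)

    def test_seeded_noise_reproducible(self):
        params = MemoryParams(s_act=0.4)
        chunk = exemplar(list("abcdef"), [0.0])
        draws = [
            activation(chunk, list("abcdef"), 1.0, params, np.random.default_rng(7))
            for _ in range(2)
        ]
        assert draws[0] == draws[1]


class TestRetrievalEquations:
    def test_probability_at_threshold_is_half(self):
        assert retrieval_probability(0.0, 0.0, 0.3) == pytest.approx(0.5)

    def test_probability_one_noise_unit_above(self):
        assert retrieval_probability(1.0, 0.0, 1.0) == pytest.approx(0.7311, abs=1e-4)

    def test_probability_monotone_and_bounded(self):
        ps = [retrieval_probability(a, 0.0, 0.5) for a in np.linspace(-5, 5, 21)]
        assert all(0 < p < 1 for p in ps)
        assert ps == sorted(ps)

    def test_probability_requires_positive_noise(self):
        with pytest.raises(MemoryError_):
            retrieval_probability(1.0, 0.0, 0.0)

    @pytest.mark.parametrize(
        "A, expected", [(0.0, 1.0), (2.0, 0.1353), (4.0, 0.0183)]
    )
    def test_latency(self, A, expected):
        assert retrieval_latency(A, 1.0) == pytest.approx(expected, abs=1e-4)


class TestRetrieve:
    def test_empty_store_fails_not_raises(self, rng):
        params = MemoryParams(s_act=0.0)
        result = DeclarativeMemory().retrieve("exemplar", 1.0, params, rng, probe=["a"] * 6)
        assert not result.success
        assert result.latency_s == pytest.approx(params.F * math.exp(-params.tau))

    def test_deterministic_success_and_latency(self, rng):
        """One chunk at noise-free activation ln(1.5)+2 > 0: retrieved, with
        the activation-determined latency."""
        params = MemoryParams(s_act=0.0)
        store = DeclarativeMemory([exemplar(list("abcdxy"), [0.0, 3.0])])
        result = store.retrieve("exemplar", 4.0, params, rng, probe=list("abcdef"))
        assert result.success
        assert result.latency_s == pytest.approx(math.exp(-(math.log(1.5) + 2.0)))

    def test_deterministic_subthreshold_failure(self, rng):
        # 2/6 match: partial match -2, base level ~0 -> activation < tau.
        params = MemoryParams(s_act=0.0)
        store = DeclarativeMemory([exemplar(list("abwxyz"), [0.0])])
        result = store.retrieve("exemplar", 1.0, params, rng, probe=list("abcdef"))
        assert not result.success

    def test_monte_carlo_matches_closed_form(self, rng):
        """Empirical retrieval frequency of a lone chunk tracks the logistic
        retrieval-probability equation within 3 binomial SEs."""
        params = MemoryParams(s_act=0.4)
        chunk = exemplar(list("abcdxy"), [0.0])  # 4/6 match -> PM +2
        n = 10_000
        for dt, probe in [(30.0, list("abcdef")), (30.0, list("abwxyz"))]:
            a_det = base_level(chunk, dt) + partial_match(probe, chunk, params)
            p = retrieval_probability(a_det, params.tau, params.s_act)
            store = DeclarativeMemory([chunk])
            hits = sum(
                store.retrieve("exemplar", dt, params, rng, probe=probe).success
                for _ in range(n)
            )
            se = math.sqrt(p * (1 - p) / n)
            assert abs(hits / n - p) < 3 * se

    def test_mean_success_latency_decreases_with_activation(self, rng):
        params = MemoryParams(s_act=0.3)
        probes = [list("abcdef"), list("abcdex")]  # 6/6 vs 5/6 match
        means = []
        for probe in probes:
            store = DeclarativeMemory([exemplar(list("abcdef"), [0.0])])
            lat = [
                r.latency_s
                for _ in range(4000)
                if (r := store.retrieve("exemplar", 10.0, params, rng, probe=probe)).success
            ]
            means.append(np.mean(lat))
        assert means[0] < means[1]

    def test_trace_deterministic_under_seed(self):
        params = MemoryParams(s_act=0.5)
        chunks = [exemplar(list("abcdef"), [0.0], f"c{i}") for i in range(5)]
        traces = []
        for _ in range(2):
            store = DeclarativeMemory(chunks)
            rng = np.random.default_rng(42)
            traces.append(
                [
                    (r.success, r.activation, r.latency_s)
                    for _ in range(50)
                    for r in [store.retrieve("exemplar", 5.0, params, rng, probe=list("abcdef"))]
                ]
            )
        assert traces[0] == traces[1]
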