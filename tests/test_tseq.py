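"""Temporal-sequence extraction, similarity, basis decomposition, classes."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tseqnet import (
    TSeqSet,
    TemporalSequence,
    canonicalize,
    class_interaction_counts,
    decompose_basis,
    extract_tseqs,
    lcs_match_fraction,
    pairwise_match_fraction,
    recompose,
    similarity_count,
    similarity_table,
)
from tseqnet import fixtures as fx
from tseqnet.fixtures import oracle_enumerate_paths
from tseqnet.tseq import PathExplosionError


def _labels(tseqs):
    return sorted(s.nodes for s in tseqs)


def _as_set(seqs, start="S", ends=("E",)):
    """Wrap bare label tuples into a TSeqSet with dummy increasing steps."""
    uniq = []
    for i, labels in enumerate(seqs):
        steps = tuple(t + i for t in range(len(labels)))
        uniq.append(TemporalSequence(nodes=tuple(labels), steps=steps))
    return TSeqSet(sequences=tuple(uniq), start_node=start,
                   end_nodes=frozenset(ends))


class TestExtract:
    def test_chain_single_sequence(self, chain_fixture):
        ts = extract_tseqs(chain_fixture.run(), "N0", {"N2"})
        assert _labels(ts) == [("N0", "N1", "N2")]

    def test_diamond_two_sequences(self, diamond_fixture):
        ts = extract_tseqs(diamond_fixture.run(), "A", {"D"})
        assert _labels(ts) == [("A", "B", "D"), ("A", "C", "D")]

    def test_cycle_laps_yield_growing_sequences(self, cycle_fixture):
        ts = extract_tseqs(cycle_fixture.run(), "A", {"E"})
        assert set(_labels(ts)) == set(cycle_fixture.expected_tseq_labels)
        assert len(ts) == 3

    def test_walks_through_end_node_yield_longer_sequences(self):
        # chain where the middle node is itself an end node
        f = fx.make_chain(4, delays=[1, 1, 1])
        ts = extract_tseqs(f.run(), "N0", {"N1", "N3"})
        assert _labels(ts) == [("N0", "N1"), ("N0", "N1", "N2", "N3")]

    def test_missing_root_raises(self, chain_fixture):
        with pytest.raises(ValueError, match="no root event"):
            extract_tseqs(chain_fixture.run(), "N2", {"N2"})

    def test_max_paths_fails_loudly(self, cycle_fixture):
        with pytest.raises(PathExplosionError):
            extract_tseqs(cycle_fixture.run(), "A", {"E"}, max_paths=1)

    def test_dedupe_labels_collapses_timing_variants(self):
        # diamond with unequal branch delays: D fires twice via two paths
        # tracing distinct labels; with equal labels they would collapse
        f = fx.make_diamond()
        ts_full = extract_tseqs(f.run(), "A", {"D"})
        ts_dedup = extract_tseqs(f.run(), "A", {"D"}, dedupe_labels=True)
        assert len(ts_full) == len(ts_dedup) == 2  # labels already distinct

    def test_sequences_validate_edges_and_delays(self):
        fixture = fx.make_random_geometric(n=14, p=0.18, seed=3, n_steps=40)
        log = fixture.run()
        ts = extract_tseqs(log, fixture.start_node, fixture.end_nodes,
                           max_paths=50000)
        edge_set = fixture.network.edge_set()
        assert len(ts) > 0
        for seq in ts:
            for (u, su), (v, sv) in zip(
                zip(seq.nodes, seq.steps), zip(seq.nodes[1:], seq.steps[1:])
            ):
                assert (u, v) in edge_set
                assert sv - su == fixture.delays[(u, v)]


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(100))
    def test_forward_extraction_equals_backward_oracle(self, seed):
        fixture = fx.make_random_geometric(
            n=14, p=0.18, seed=seed, n_steps=40,
            inhibitory_fraction=0.15,
        )
        log = fixture.run()
        try:
            ts = extract_tseqs(log, fixture.start_node, fixture.end_nodes,
                               max_paths=20000)
        except PathExplosionError:
            pytest.skip("path explosion at this seed")
        oracle = oracle_enumerate_paths(log, fixture.start_node,
                                        fixture.end_nodes, limit=20000)
        assert {(s.nodes, s.steps) for s in ts} == {
            (s.nodes, s.steps) for s in oracle
        }


class TestMatchFraction:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            (("A", "B", "C"), ("A", "B", "C"), 1.0),
            (("A", "B"), ("B", "A"), 0.5),
            (("A", "B", "C", "D", "E"), ("A", "B", "C", "D", "X"), 0.8),
            (("A", "B"), ("C", "D"), 0.0),
            (("A",), ("X", "A", "X"), 1.0),
            (("A", "A"), ("A",), 0.5),
        ],
    )
    def test_hand_traced_values(self, x, y, expected):
        assert pairwise_match_fraction(x, y) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_match_fraction((), ("A",))

    @given(
        x=st.lists(st.sampled_from("ABCD"), min_size=1, max_size=8),
        y=st.lists(st.sampled_from("ABCD"), min_size=1, max_size=8),
        suffix=st.lists(st.sampled_from("ABCD"), max_size=4),
    )
    @settings(max_examples=200, derandomize=True)
    def test_properties(self, x, y, suffix):
        f = pairwise_match_fraction(x, y)
        assert 0.0 <= f <= 1.0
        assert pairwise_match_fraction(x, x) == 1.0
        # greedy never beats the maximal in-order match
        assert f <= lcs_match_fraction(x, y) + 1e-12
        # the count of matched labels never decreases under suffix extension
        # when the suffix cannot steal an earlier match (disjoint labels);
        # unrestricted suffixes CAN lower the greedy fraction (e.g. x=BAA,
        # y=AA, suffix=B: the B match advances the cursor past both As)
        if not set(suffix) & set(x):
            assert pairwise_match_fraction(x, y + suffix) == pytest.approx(f)


class TestSimilarityCounts:
    def test_self_similarity_is_set_size(self, cycle_fixture):
        ts = extract_tseqs(cycle_fixture.run(), "A", {"E"})
        assert similarity_count(ts, ts, 1.0) == len(ts)

    def test_zero_threshold_counts_everything(self, cycle_fixture, diamond_fixture):
        X = extract_tseqs(cycle_fixture.run(), "A", {"E"})
        Y = extract_tseqs(diamond_fixture.run(), "A", {"D"})
        assert similarity_count(X, Y, 0.0) == len(X)

    def test_exhaustive_pairwise_example(self):
        X = _as_set([("A", "B"), ("C", "D")])
        Y = _as_set([("A", "E", "B")])
        assert similarity_count(X, Y, 1.0) == 1

    def test_empty_reference_rejected(self):
        Y = _as_set([("A",)])
        with pytest.raises(ValueError, match="empty"):
            similarity_count([], Y, 0.5)

    def test_table_monotone_and_anchored(self, cycle_fixture):
        ts = extract_tseqs(cycle_fixture.run(), "A", {"E"})
        table = similarity_table(ts, ts)
        assert table.counts[0] == len(ts)  # alpha = 0 row
        assert all(
            c2 <= c1 for c1, c2 in zip(table.counts, table.counts[1:])
        )
        assert set(table.counts) == {len(ts)}  # X vs X: all rows full

    @pytest.mark.parametrize("seed", range(10))
    def test_count_matches_brute_force_max(self, seed):
        rng = np.random.default_rng(seed)
        mk = lambda: tuple(rng.choice(list("ABCDE"), size=rng.integers(1, 6)))
        X = [mk() for _ in range(6)]
        Y = [mk() for _ in range(6)]
        for alpha in (0.0, 0.3, 0.6, 1.0):
            brute = sum(
                1
                for x in X
                if max(pairwise_match_fraction(x, y) for y in Y) >= alpha
            )
            assert similarity_count(X, Y, alpha) == brute


class TestCanonicalize:
    @pytest.mark.parametrize(
        "labels,units,canonical",
        [
            (("A", "B", "A", "B", "C"),
             ((("A", "B"), 2), (("C",), 1)), ("A", "B", "C")),
            (("A", "A", "A"), ((("A",), 3),), ("A",)),
            (("A", "B", "C"), ((("A", "B", "C"), 1),), ("A", "B", "C")),
        ],
    )
    def test_known_compressions(self, labels, units, canonical):
        c = canonicalize(labels)
        assert c.units == units
        assert c.canonical == canonical

    def test_nested_repeat_reaches_fixed_point(self):
        c = canonicalize(("A", "A", "B", "A", "A", "B"))
        assert c.canonical == ("A", "B")
        assert recompose(c) == ("A", "A", "B", "A", "A", "B")

    def test_recompose_with_counts(self):
        c = canonicalize(("A", "B", "A", "B", "C"))
        assert recompose(c, (3, 1)) == ("A", "B", "A", "B", "A", "B", "C")

    def test_count_arity_mismatch(self):
        c = canonicalize(("A", "B"))
        with pytest.raises(ValueError, match="counts"):
            recompose(c, (1, 2, 3))

    @given(
        st.lists(st.sampled_from("ABC"), min_size=1, max_size=12)
    )
    @settings(max_examples=500, derandomize=True)
    def test_round_trip_identity_fuzzed(self, labels):
        labels = tuple(labels)
        c = canonicalize(labels)
        assert recompose(c) == labels
        # canonical form is repeat-free at the fixed point
        c2 = canonicalize(c.canonical)
        assert c2.canonical == c.canonical


class TestBasis:
    def test_repetition_variants_group_together(self):
        X = _as_set([("A", "B", "A", "B", "C"),
                     ("A", "B", "A", "B", "A", "B", "C")])
        basis = decompose_basis(X)
        assert basis.n_one_time == 0
        assert basis.n_repeating_groups == 1
        assert basis.n_repeating_members == 2

    def test_distinct_repeat_free_sequences_are_one_time(self):
        X = _as_set([("A", "B"), ("C", "D"), ("E",)])
        basis = decompose_basis(X)
        assert basis.n_one_time == 3
        assert basis.n_repeating_groups == 0

    def test_partition_property(self, cycle_fixture):
        ts = extract_tseqs(cycle_fixture.run(), "A", {"E"})
        basis = decompose_basis(ts)
        assert basis.n_one_time + basis.n_repeating_members == len(ts)
        one_time_keys = {s.nodes for s in basis.one_time}
        repeating_keys = {
            m.nodes
            for members in basis.repeating_groups.values()
            for m, _ in members
        }
        assert not one_time_keys & repeating_keys

    def test_cycle_laps_form_single_group(self, cycle_fixture):
        # the three lap-variants differ only in (B, A) repetitions
        ts = extract_tseqs(cycle_fixture.run(), "A", {"E"})
        basis = decompose_basis(ts)
        assert basis.n_repeating_groups == 1
        assert basis.n_repeating_members == 3
        assert basis.n_one_time == 0

    def test_group_members_reexpand(self):
        X = _as_set([("A", "B", "A", "B", "C"),
                     ("A", "B", "A", "B", "A", "B", "C")])
        basis = decompose_basis(X)
        for members in basis.repeating_groups.values():
            for member, compressed in members:
                assert recompose(compressed) == member.nodes


class TestClassInteractions:
    CLASS_MAP = {
        "a1": "VA", "b1": "VB", "b2": "VB", "d1": "DB", "x": None, "s": None,
    }

    def test_single_pair_by_hand(self):
        X = _as_set([("s", "a1", "b1")])
        counts = class_interaction_counts(X, self.CLASS_MAP,
                                          ["VA", "VB", "DB"], k=2)
        assert counts[frozenset({"VA", "VB"})] == 1
        assert counts[frozenset({"VA", "DB"})] == 0
        assert counts[frozenset({"VB", "DB"})] == 0

    def test_k_beyond_any_sequence_is_zero(self):
        X = _as_set([("s", "a1", "b1")])
        counts = class_interaction_counts(X, self.CLASS_MAP,
                                          ["VA", "VB", "DB"], k=3)
        assert set(counts.values()) == {0}

    def test_unknown_class_rejected(self):
        X = _as_set([("s", "a1")])
        with pytest.raises(ValueError, match="absent"):
            class_interaction_counts(X, self.CLASS_MAP, ["ZZ"], k=1)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_subset_scan(self, seed):
        rng = np.random.default_rng(seed)
        nodes = list(self.CLASS_MAP)
        X = _as_set(
            [tuple(rng.choice(nodes, size=rng.integers(1, 6))) for _ in range(10)],
            ends=nodes,
        )
        classes = ["VA", "VB", "DB"]
        for k in (1, 2, 3):
            counts = class_interaction_counts(X, self.CLASS_MAP, classes, k)
            for sub in itertools.combinations(classes, k):
                brute = sum(
                    1
                    for s in X
                    if set(sub)
                    <= {self.CLASS_MAP.get(n) for n in s.nodes}
                )
                assert counts[frozenset(sub)] == brute
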