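"""Tests for propagation, pruning and color resolution."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontoburst import (
    ColorScale,
    ConfigError,
    FixtureSpec,
    OntologyKind,
    PropagationConfig,
    TermRecord,
    assign_colors,
    build_forest,
    drop_empty,
    generate_forest_records,
    interpolate_color,
    propagate_counts,
)
from conftest import propagation_oracle, prune_oracle


def generic_forest(counts: dict[str, float]):
    return build_forest(
        [TermRecord(code, count=c) for code, c in counts.items()],
        OntologyKind.GENERIC,
    )


class TestPropagateCounts:
    def test_children_sum_into_parent(self):
        forest = generic_forest({"A": 0, "A.B": 2, "A.C": 3})
        out = propagate_counts(forest, PropagationConfig(max_level=1))
        assert out.find("A").propagated_count == 5

    def test_chain_full_propagation(self):
        forest = generic_forest({"A": 1, "A.B": 1, "A.B.C": 1})
        out = propagate_counts(forest, PropagationConfig(max_level=1))
        assert out.find("A").propagated_count == 3
        assert out.find("A.B").propagated_count == 2
        assert out.find("A.B.C").propagated_count == 1

    def test_chain_propagation_capped_at_level_2(self):
        forest = generic_forest({"A": 1, "A.B": 1, "A.B.C": 1})
        out = propagate_counts(forest, PropagationConfig(max_level=2))
        assert out.find("A").propagated_count == 1  # shallower than cap: raw
        assert out.find("A.B").propagated_count == 2
        assert out.find("A.B.C").propagated_count == 1

    def test_disabled_is_identity(self, mini_forest):
        out = propagate_counts(mini_forest, PropagationConfig(enabled=False))
        for node in out.iter_nodes():
            assert node.propagated_count == node.raw_count

    def test_does_not_mutate_input(self, mini_forest):
        before = [(n.code, n.propagated_count) for n in mini_forest.iter_nodes()]
        propagate_counts(mini_forest, PropagationConfig(max_level=1))
        assert [(n.code, n.propagated_count) for n in mini_forest.iter_nodes()] == before

    def test_exclude_self_drops_interior_raw_counts(self):
        forest = generic_forest({"A": 10, "A.B": 2, "A.C": 3})
        out = propagate_counts(
            forest, PropagationConfig(max_level=1, include_self=False)
        )
        # interior nodes report pure child sums (their own raw count is
        # dropped -- the documented hazard of include_self=False); leaves
        # keep their raw count
        assert out.find("A").propagated_count == 5
        assert out.find("A.B").propagated_count == 2
        assert out.find("A.C").propagated_count == 3

    def test_matches_oracle_on_mini_fixture(self, mini_forest):
        for max_level in (1, 2, 3, 4, 5):
            out = propagate_counts(mini_forest, PropagationConfig(max_level=max_level))
            expected = propagation_oracle(mini_forest, max_level)
            got = {n.code: n.propagated_count for n in out.iter_nodes()}
            assert got == expected

    def test_propagated_at_least_raw(self, mini_forest):
        out = propagate_counts(mini_forest, PropagationConfig(max_level=1))
        for node in out.iter_nodes():
            assert node.propagated_count >= node.raw_count

    def test_bad_max_level_rejected(self):
        with pytest.raises(ConfigError):
            PropagationConfig(max_level=0)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), max_level=st.integers(1, 5))
    def test_matches_oracle_on_random_forests(self, seed, max_level):
        records = generate_forest_records(
            FixtureSpec(n_roots=2, depth=4, branching=(1, 3), seed=seed)
        )
        forest = build_forest(records, OntologyKind.GENERIC)
        out = propagate_counts(forest, PropagationConfig(max_level=max_level))
        assert {n.code: n.propagated_count for n in out.iter_nodes()} == (
            propagation_oracle(forest, max_level)
        )

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_idempotent(self, seed):
        records = generate_forest_records(FixtureSpec(seed=seed))
        forest = build_forest(records, OntologyKind.GENERIC)
        once = propagate_counts(forest, PropagationConfig(max_level=1))
        twice = propagate_counts(once, PropagationConfig(max_level=1))
        assert [n.propagated_count for n in once.iter_nodes()] == [
            n.propagated_count for n in twice.iter_nodes()
        ]


class TestDropEmpty:
    def test_zero_leaf_removed_parent_kept(self):
        forest = generic_forest({"A": 4, "A.B": 0})
        out = drop_empty(forest)
        assert out.find("A") is not None
        assert out.find("A.B") is None

    def test_all_zero_subtree_removed_including_root(self):
        forest = generic_forest({"A": 1, "A.B": 0, "A.B.C": 0, "A.D": 2})
        out = drop_empty(forest)
        assert {n.code for n in out.iter_nodes()} == {"A", "A.D"}

    def test_all_positive_unchanged(self):
        forest = generic_forest({"A": 1, "A.B": 2})
        out = drop_empty(forest)
        assert {n.code for n in out.iter_nodes()} == {"A", "A.B"}

    def test_zero_interior_with_nonzero_child_kept(self):
        forest = generic_forest({"A": 0, "A.B": 3})
        out = drop_empty(forest)
        assert out.find("A") is not None

    def test_entirely_empty_forest_becomes_empty(self):
        forest = generic_forest({"A": 0, "A.B": 0})
        assert drop_empty(forest).roots == []

    def test_decoy_leaf_removed_from_mini_fixture(self, mini_forest):
        out = drop_empty(mini_forest)
        assert out.find("J05AB09") is None
        assert out.find("J05AB01") is not None

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_reachability_oracle(self, seed):
        records = generate_forest_records(
            FixtureSpec(zero_inflation=0.6, seed=seed)
        )
        forest = build_forest(records, OntologyKind.GENERIC)
        out = drop_empty(forest)
        assert {n.code for n in out.iter_nodes()} == prune_oracle(forest)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_idempotent_and_preserves_positive_nodes(self, seed):
        records = generate_forest_records(FixtureSpec(zero_inflation=0.7, seed=seed))
        forest = build_forest(records, OntologyKind.GENERIC)
        once = drop_empty(forest)
        twice = drop_empty(once)
        assert {n.code for n in once.iter_nodes()} == {n.code for n in twice.iter_nodes()}
        positive = {n.code for n in forest.iter_nodes() if n.propagated_count > 0}
        assert positive <= {n.code for n in once.iter_nodes()}


class TestPipelineOrder:
    def test_prune_then_propagate_differs_without_include_self(self):
        # An annotated interior node whose children are all empty: pruning
        # first turns it into a leaf that keeps its raw count, while
        # propagating first (child sums only) zeroes it and pruning then
        # removes the whole subtree.
        counts = {"A": 3, "A.B": 0}
        config = PropagationConfig(max_level=1, include_self=False)

        forest = generic_forest(counts)
        prop_first = drop_empty(propagate_counts(forest, config))
        prune_first = propagate_counts(drop_empty(forest), config)

        assert [n.code for n in prop_first.iter_nodes()] == []
        assert [(n.code, n.propagated_count) for n in prune_first.iter_nodes()] == [
            ("A", 3.0)
        ]

    def test_default_pipeline_keeps_interior_annotations(self):
        forest = generic_forest({"A": 3, "A.B": 0})
        out = drop_empty(propagate_counts(forest, PropagationConfig(max_level=1)))
        assert [(n.code, n.propagated_count) for n in out.iter_nodes()] == [("A", 3.0)]


WHITE_RED = ColorScale.white_to_red()


class TestInterpolateColor:
    def test_endpoints_exact(self):
        assert interpolate_color(WHITE_RED, 0.0) == "#FFFFFF"
        assert interpolate_color(WHITE_RED, 1.0) == "#FF0000"

    def test_midpoint(self):
        assert interpolate_color(WHITE_RED, 0.5) == "#FF8080"

    def test_every_stop_exact_in_multistop_scale(self):
        scale = ColorScale(((0.0, "#000000"), (0.25, "#123456"), (1.0, "#FFFFFF")))
        assert interpolate_color(scale, 0.25) == "#123456"
        assert interpolate_color(scale, 0.0) == "#000000"
        assert interpolate_color(scale, 1.0) == "#FFFFFF"

    @pytest.mark.parametrize("v", [-0.1, 1.1])
    def test_domain_error(self, v):
        with pytest.raises(ConfigError):
            interpolate_color(WHITE_RED, v)

    def test_result_is_uppercase(self):
        scale = ColorScale(((0.0, "#0a0b0c"), (1.0, "#fafbfc")))
        assert interpolate_color(scale, 0.3) == interpolate_color(scale, 0.3).upper()

    @settings(max_examples=60, deadline=None)
    @given(
        a=st.floats(0, 1, allow_nan=False),
        b=st.floats(0, 1, allow_nan=False),
    )
    def test_monotone_per_channel(self, a, b):
        lo, hi = sorted((a, b))
        c_lo = interpolate_color(WHITE_RED, lo)
        c_hi = interpolate_color(WHITE_RED, hi)
        # white -> red: red channel constant, green/blue non-increasing
        assert int(c_lo[3:5], 16) >= int(c_hi[3:5], 16)
        assert int(c_lo[5:7], 16) >= int(c_hi[5:7], 16)


class TestColorScaleValidation:
    def test_too_few_stops(self):
        with pytest.raises(ConfigError):
            ColorScale(((0.0, "#FFFFFF"),))

    def test_positions_must_cover_unit_interval(self):
        with pytest.raises(ConfigError):
            ColorScale(((0.1, "#FFFFFF"), (1.0, "#FF0000")))

    def test_positions_strictly_increasing(self):
        with pytest.raises(ConfigError):
            ColorScale(((0.0, "#FFFFFF"), (0.5, "#FF0000"), (0.5, "#000000"), (1.0, "#00FF00")))

    def test_from_string(self):
        scale = ColorScale.from_string("0:#FFFFFF,0.5:#FFFF00,1:#FF0000")
        assert scale.stops == ((0.0, "#FFFFFF"), (0.5, "#FFFF00"), (1.0, "#FF0000"))


class TestAssignColors:
    def test_normalized_palette(self):
        forest = generic_forest({"A": 0, "A.B": 5, "A.C": 10})
        out = assign_colors(forest, WHITE_RED)
        assert out.find("A").color == "#FFFFFF"
        assert out.find("A.B").color == "#FF8080"
        assert out.find("A.C").color == "#FF0000"

    def test_manual_color_overrides_automatic(self):
        forest = build_forest(
            [TermRecord("A", count=100, color="#00FF00"), TermRecord("A.B", count=1)],
            OntologyKind.GENERIC,
        )
        out = assign_colors(forest, WHITE_RED)
        assert out.find("A").color == "#00FF00"

    def test_all_zero_forest_gets_position_zero_color(self):
        forest = generic_forest({"A": 0, "A.B": 0})
        out = assign_colors(forest, WHITE_RED)
        assert {n.color for n in out.iter_nodes()} == {"#FFFFFF"}

    def test_per_branch_normalization(self):
        forest = generic_forest({"A": 10, "B": 2})
        out = assign_colors(forest, WHITE_RED, per_branch=True)
        # each branch max is its own root -> both fully saturated
        assert out.find("A").color == "#FF0000"
        assert out.find("B").color == "#FF0000"
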