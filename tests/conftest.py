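"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately use different algorithms from the library code
they check: propagation is verified against a naive recursive subtree sum,
and pruning against a literal iterate-until-fixpoint leaf remover.
"""

from __future__ import annotations

import pytest

from ontoburst import OntologyKind, build_forest, make_mini_atc
from ontoburst.model import OntologyForest, OntologyNode


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def subtree_sum(node: OntologyNode) -> float:
    """Brute-force recursive sum of raw counts over a subtree."""
    return node.raw_count + sum(subtree_sum(c) for c in node.children)


def propagation_oracle(forest: OntologyForest, max_level: int = 1) -> dict[str, float]:
    """Expected propagated count per code, via the recursive subtree sum.

    Nodes at or below ``max_level`` depth receive the full subtree sum;
    shallower nodes keep their raw count.
    """
    expected: dict[str, float] = {}
    for node in forest.iter_nodes():
        if node.level >= max_level:
            expected[node.code] = subtree_sum(node)
        else:
            expected[node.code] = node.raw_count
    return expected


def prune_oracle(forest: OntologyForest) -> set[str]:
    """Surviving codes after literally removing zero-count leaves to fixpoint."""
    counts = {n.code: n.propagated_count for n in forest.iter_nodes()}
    parent_of: dict[str, str | None] = {}

    def walk(node: OntologyNode, parent: str | None) -> None:
        parent_of[node.code] = parent
        for child in node.children:
            walk(child, node.code)

    for root in forest.roots:
        walk(root, None)

    alive = set(counts)
    changed = True
    while changed:
        changed = False
        has_children = {parent_of[c] for c in alive if parent_of[c] is not None}
        for code in list(alive):
            if code not in has_children and counts[code] == 0:
                alive.discard(code)
                changed = True
    return alive


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

@pytest.fixture
def mini_records():
    return make_mini_atc()


@pytest.fixture
def mini_forest(mini_records):
    return build_forest(mini_records, OntologyKind.ATC)
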