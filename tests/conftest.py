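"""Shared fixtures and independent brute-force oracles.

The oracles enumerate matchings explicitly (backtracking over the edge
list) and are deliberately independent of the implementation under test:
they define maximum matchings, the critical/redundant/ordinary partition
and the cardinality-then-weight objective from first principles on graphs
small enough to enumerate.
"""

from __future__ import annotations

import random

import pytest

from copath import DirectedLayer


@pytest.fixture
def toy_layer() -> DirectedLayer:
    """The five-node toy digraph used throughout: 1->2, 2->3, 2->4, 2->5, 4->5."""
    return DirectedLayer(
        "toy",
        nodes={"1", "2", "3", "4", "5"},
        edges={("1", "2"), ("2", "3"), ("2", "4"), ("2", "5"), ("4", "5")},
    )


# ---------------------------------------------------------------------------
# enumeration oracles (small graphs only)


def enumerate_maximum_matchings(edges):
    """All maximum matchings of a directed edge set, by explicit backtracking.

    Returns (max_cardinality, set of frozensets of edges).
    """
    edges = sorted(edges)
    best_size = 0
    best: set[frozenset] = {frozenset()}

    def rec(i, used_t, used_h, cur):
        nonlocal best_size, best
        if i == len(edges):
            if len(cur) > best_size:
                best_size = len(cur)
                best = {frozenset(cur)}
            elif len(cur) == best_size:
                best.add(frozenset(cur))
            return
        u, v = edges[i]
        rec(i + 1, used_t, used_h, cur)
        if u not in used_t and v not in used_h:
            cur.append((u, v))
            rec(i + 1, used_t | {u}, used_h | {v}, cur)
            cur.pop()

    rec(0, set(), set(), [])
    return best_size, best


def classify_by_enumeration(edges):
    """critical / redundant / ordinary sets straight from the definition."""
    _, matchings = enumerate_maximum_matchings(edges)
    edges = set(edges)
    critical = {e for e in edges if all(e in m for m in matchings)}
    redundant = {e for e in edges if all(e not in m for m in matchings)}
    ordinary = edges - critical - redundant
    return critical, redundant, ordinary


def best_matching_by_enumeration(edges, weights):
    """Lexicographically best (cardinality, total weight) over all matchings."""
    edges = sorted(edges)
    best = (0, 0.0)

    def rec(i, used_t, used_h, size, w):
        nonlocal best
        best = max(best, (size, w))
        for j in range(i, len(edges)):
            u, v = edges[j]
            if u not in used_t and v not in used_h:
                rec(j + 1, used_t | {u}, used_h | {v},
                    size + 1, w + weights[(u, v)])

    rec(0, set(), set(), 0, 0.0)
    return best


def random_layer(rng: random.Random, max_nodes: int = 8,
                 allow_self_loops: bool = False) -> DirectedLayer:
    """A small random digraph for oracle comparisons (<= 12 edges so that
    full matching enumeration stays instant)."""
    n = rng.randint(2, max_nodes)
    labels = [chr(ord("a") + i) for i in range(n)]
    possible = [
        (u, v) for u in labels for v in labels
        if allow_self_loops or u != v
    ]
    m = rng.randint(0, min(12, len(possible)))
    edges = set(rng.sample(possible, m))
    return DirectedLayer("rand", nodes=set(labels), edges=edges)
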