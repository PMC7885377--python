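"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: closures by full extent scans,
concept enumeration over all 2^m attribute subsets, covering edges from the
pairwise-inclusion definition, trajectory enumeration by exhaustive DFS.
None of it shares code with the package's algorithms.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from healthtraj.fca import Concept, FormalContext


def brute_closure(context: FormalContext, attrs: frozenset[str]) -> frozenset[str]:
    """attrs -> objects having all of them -> attributes they all share."""
    rows = [
        i
        for i, _ in enumerate(context.objects)
        if all(context.incidence[i, context.attributes.index(a)] for a in attrs)
    ]
    if not rows:
        return frozenset(context.attributes)
    shared = set(context.attributes)
    for i in rows:
        shared &= {
            a for j, a in enumerate(context.attributes) if context.incidence[i, j]
        }
    return frozenset(shared)


def brute_extent(context: FormalContext, attrs: frozenset[str]) -> frozenset[str]:
    return frozenset(
        o
        for i, o in enumerate(context.objects)
        if all(context.incidence[i, context.attributes.index(a)] for a in attrs)
    )


def brute_concepts(context: FormalContext) -> set[Concept]:
    """All concepts by scanning every attribute subset for closedness."""
    out = set()
    attrs = context.attributes
    for r in range(len(attrs) + 1):
        for combo in combinations(attrs, r):
            subset = frozenset(combo)
            closed = brute_closure(context, subset)
            if closed == subset:
                out.add(Concept(brute_extent(context, subset), subset))
    return out


def brute_covering_edges(concepts: list[Concept]) -> set[tuple[int, int]]:
    """Covering pairs straight from the definition of the Hasse diagram."""
    n = len(concepts)
    edges = set()
    for i in range(n):
        for j in range(n):
            if not concepts[i].intent < concepts[j].intent:
                continue
            between = any(
                concepts[i].intent < concepts[k].intent < concepts[j].intent
                for k in range(n)
            )
            if not between:
                edges.add((i, j))
    return edges


def brute_trajectories(concepts, risks, start, max_len, tol=1e-12):
    """All strictly-risk-decreasing covering chains by exhaustive DFS.

    ``risks`` maps intent -> smoothed risk (only nonempty-extent concepts).
    Returns a set of intent-sequence tuples.
    """
    covering = {}
    for i, j in brute_covering_edges(concepts):
        covering.setdefault(concepts[i].intent, []).append(concepts[j].intent)

    chains = set()

    def rec(path):
        chains.add(tuple(path))
        if len(path) - 1 >= max_len:
            return
        for nxt in covering.get(path[-1], []):
            if nxt in risks and risks[nxt] < risks[path[-1]] - tol:
                rec(path + [nxt])

    rec([start.intent])
    return chains


def random_context(rng: np.random.Generator, n_objects: int, n_attrs: int,
                   density: float = 0.5, event_rate: float = 0.2) -> FormalContext:
    """A random binary context with random outcome labels."""
    incidence = rng.random((n_objects, n_attrs)) < density
    outcome = rng.random(n_objects) < event_rate
    objects = [f"o{i}" for i in range(n_objects)]
    attributes = [chr(ord("A") + j) for j in range(n_attrs)]
    return FormalContext(objects, attributes, incidence, outcome)
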