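"""Formal concept analysis core: context, concepts, lattice.

Patients are the objects of a formal context and binary positive lifestyle
factors are its attributes.  A formal concept is a maximal pair
(extent = patient set, intent = factor set) closed under the Galois
connection; the set of all concepts ordered by intent inclusion is the
concept lattice, whose covering edges are the arrows of the trajectory
network.  Enumeration uses Ganter's NextClosure algorithm in lectic order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from ._util import HealthTrajError

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import FactorVector

#: 2^|attributes| candidate intents must stay enumerable; the method is
#: designed for a handful of binary factors.
MAX_ATTRIBUTES = 16


class ContextError(HealthTrajError):
    """Invalid formal context or attribute set."""


# ---------------------------------------------------------------------------
# Context
# ---------------------------------------------------------------------------


class FormalContext:
    """Patients × binary-factors incidence structure with outcome labels.

    Parameters
    ----------
    objects:
        Ordered patient ids (unique).
    attributes:
        Ordered factor names (unique, at most ``MAX_ATTRIBUTES``).
    incidence:
        Boolean matrix, ``incidence[i, j]`` true iff object i has attribute j.
    outcome:
        Per-object binary event label (early reoperation).
    """

    def __init__(
        self,
        objects: Sequence[str],
        attributes: Sequence[str],
        incidence: np.ndarray,
        outcome: Sequence[bool] | np.ndarray | None = None,
    ) -> None:
        self.objects = list(objects)
        self.attributes = list(attributes)
        if len(set(self.objects)) != len(self.objects):
            raise ContextError("duplicate object (patient) ids")
        if len(set(self.attributes)) != len(self.attributes):
            raise ContextError("duplicate attribute names")
        if not self.attributes:
            raise ContextError("attribute universe must be nonempty")
        if len(self.attributes) > MAX_ATTRIBUTES:
            raise ContextError(
                f"{len(self.attributes)} attributes exceed the supported maximum of "
                f"{MAX_ATTRIBUTES}; select a smaller factor set before building the context"
            )
        self.incidence = np.asarray(incidence, dtype=bool)
        if self.incidence.shape != (len(self.objects), len(self.attributes)):
            raise ContextError(
                f"incidence shape {self.incidence.shape} does not match "
                f"{len(self.objects)} objects x {len(self.attributes)} attributes"
            )
        if outcome is None:
            outcome = np.zeros(len(self.objects), dtype=bool)
        self.outcome = np.asarray(outcome, dtype=bool)
        if self.outcome.shape != (len(self.objects),):
            raise ContextError("outcome must have one label per object")
        self._attr_index = {a: j for j, a in enumerate(self.attributes)}

    # -- derivation operators ------------------------------------------------

    def _attr_cols(self, attrs: Iterable[str]) -> list[int]:
        cols = []
        for a in attrs:
            if a not in self._attr_index:
                raise ContextError(f"unknown attribute {a!r}")
            cols.append(self._attr_index[a])
        return cols

    def extent_mask(self, attrs: Iterable[str]) -> np.ndarray:
        """Boolean mask of objects having every attribute in ``attrs``."""
        cols = self._attr_cols(attrs)
        if not cols:
            return np.ones(len(self.objects), dtype=bool)
        return self.incidence[:, cols].all(axis=1)

    def extent(self, attrs: Iterable[str]) -> frozenset[str]:
        mask = self.extent_mask(attrs)
        return frozenset(o for o, keep in zip(self.objects, mask) if keep)

    def intent_of_mask(self, mask: np.ndarray) -> frozenset[str]:
        """Attributes shared by every object in the mask (all of them if empty)."""
        if not mask.any():
            return frozenset(self.attributes)
        shared = self.incidence[mask].all(axis=0)
        return frozenset(a for a, keep in zip(self.attributes, shared) if keep)

    def closure(self, attrs: Iterable[str]) -> frozenset[str]:
        """Galois closure: attrs -> extent -> intent.  Idempotent, extensive."""
        return self.intent_of_mask(self.extent_mask(attrs))

    # -- serialisation -------------------------------------------------------

    def to_burmeister(self, name: str = "") -> str:
        """Serialise in the plain-text Burmeister context format."""
        lines = ["B", name, str(len(self.objects)), str(len(self.attributes)), ""]
        lines.extend(self.objects)
        lines.extend(self.attributes)
        for row in self.incidence:
            lines.append("".join("X" if cell else "." for cell in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_burmeister(
        cls, text: str, outcome: Sequence[bool] | None = None
    ) -> "FormalContext":
        lines = text.splitlines()
        if not lines or lines[0].strip() != "B":
            raise ContextError("not a Burmeister context (missing 'B' header)")
        body = [ln for ln in lines[1:]]
        # line 0: context name (may be blank); then counts, blank, names, grid
        rest = [ln for ln in body[1:] if ln.strip() != ""]
        n, m = int(rest[0]), int(rest[1])
        objects = rest[2 : 2 + n]
        attributes = rest[2 + n : 2 + n + m]
        grid = rest[2 + n + m : 2 + n + m + n]
        if len(grid) != n:
            raise ContextError("truncated Burmeister grid")
        incidence = np.array([[c == "X" for c in row.strip()] for row in grid], dtype=bool)
        return cls(objects, attributes, incidence, outcome)

    def to_json(self) -> str:
        return json.dumps(
            {
                "objects": self.objects,
                "attributes": self.attributes,
                "incidence": self.incidence.astype(int).tolist(),
                "outcome": self.outcome.astype(int).tolist(),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "FormalContext":
        data = json.loads(text)
        return cls(
            data["objects"],
            data["attributes"],
            np.array(data["incidence"], dtype=bool),
            np.array(data["outcome"], dtype=bool),
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"FormalContext({len(self.objects)} objects x "
            f"{len(self.attributes)} attributes)"
        )


def build_context(
    vectors: Sequence["FactorVector"],
    attribute_universe: Sequence[str] | None = None,
) -> FormalContext:
    """Build the formal context from binarised patient vectors.

    Object order follows input order; attribute order follows the given
    universe (or sorted names found in the data).  Duplicate patient ids are
    rejected.
    """
    if not vectors:
        raise ContextError("cannot build a context from an empty cohort")
    if attribute_universe is None:
        attribute_universe = sorted(set().union(*(v.factors for v in vectors)))
    attributes = list(attribute_universe)
    if not attributes:
        raise ContextError("attribute universe must be nonempty")
    universe = set(attributes)
    for v in vectors:
        unknown = v.factors - universe
        if unknown:
            raise ContextError(
                f"patient {v.patient_id} carries factor(s) outside the "
                f"attribute universe: {sorted(unknown)}"
            )
    objects = [v.patient_id for v in vectors]
    incidence = np.array(
        [[a in v.factors for a in attributes] for v in vectors], dtype=bool
    )
    outcome = np.array([v.reoperated for v in vectors], dtype=bool)
    return FormalContext(objects, attributes, incidence, outcome)


# ---------------------------------------------------------------------------
# Concepts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Concept:
    """A formal concept: (extent, intent) closed under the Galois connection."""

    extent: frozenset[str]
    intent: frozenset[str]

    def sort_key(self) -> tuple[int, tuple[str, ...]]:
        return (len(self.intent), tuple(sorted(self.intent)))


def enumerate_concepts(context: FormalContext) -> list[Concept]:
    """All formal concepts of the context, in lectic order of intents.

    NextClosure (Ganter): intents are exactly the closed attribute sets;
    they are generated in lectic order w.r.t. the attribute ordering of the
    context.  The number of concepts is at most 2^|attributes|.
    """
    attrs = context.attributes
    m = len(attrs)

    def close(idx_set: frozenset[int]) -> frozenset[int]:
        closed = context.closure(attrs[i] for i in idx_set)
        return frozenset(context._attr_index[a] for a in closed)

    concepts: list[Concept] = []

    def emit(idx_set: frozenset[int]) -> None:
        names = frozenset(attrs[i] for i in idx_set)
        concepts.append(Concept(context.extent(names), names))

    current = close(frozenset())
    emit(current)
    full = frozenset(range(m))
    while current != full:
        for i in reversed(range(m)):
            if i in current:
                continue
            candidate = close(frozenset(j for j in current if j < i) | {i})
            # lectic condition: no new element below i
            if all(j in current for j in candidate if j < i):
                current = candidate
                emit(current)
                break
        else:  # pragma: no cover - full set is always closed and reached
            break
    return concepts


# ---------------------------------------------------------------------------
# Lattice
# ---------------------------------------------------------------------------


@dataclass
class ConceptLattice:
    """Concepts plus the covering relation of intent inclusion.

    ``concepts`` is sorted by (|intent|, lexicographic intent) so serialised
    output is reproducible.  ``edges`` holds (parent, child) index pairs where
    the child intent strictly contains the parent intent with no concept in
    between (the transitive reduction, i.e. the Hasse diagram).
    """

    concepts: list[Concept]
    edges: set[tuple[int, int]] = field(default_factory=set)
    children: dict[int, list[int]] = field(default_factory=dict)
    parents: dict[int, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_intent = {c.intent: i for i, c in enumerate(self.concepts)}

    def index(self, concept: Concept) -> int:
        return self._by_intent[concept.intent]

    def by_intent(self, intent: frozenset[str]) -> Concept:
        return self.concepts[self._by_intent[intent]]

    @property
    def top(self) -> Concept:
        """The most general concept (minimal intent, all patients)."""
        return self.concepts[0]

    @property
    def bottom(self) -> Concept:
        """The most specific concept (maximal intent; extent may be empty)."""
        return self.concepts[-1]

    def child_concepts(self, concept: Concept) -> list[Concept]:
        return [self.concepts[j] for j in self.children.get(self.index(concept), [])]

    def parent_concepts(self, concept: Concept) -> list[Concept]:
        return [self.concepts[j] for j in self.parents.get(self.index(concept), [])]


def build_lattice(concepts: Sequence[Concept]) -> ConceptLattice:
    """Order concepts by intent inclusion and compute covering edges.

    The input must be the complete concept set of one context (otherwise the
    unique-top/unique-bottom structure is not guaranteed).
    """
    seen = set()
    for c in concepts:
        if c.intent in seen:
            raise ContextError(f"duplicate concept with intent {sorted(c.intent)}")
        seen.add(c.intent)

    ordered = sorted(concepts, key=Concept.sort_key)
    lattice = ConceptLattice(ordered)

    n = len(ordered)
    intents = [c.intent for c in ordered]
    # subset[i][j]: intent_i strictly contained in intent_j
    subset = [
        [i != j and intents[i] < intents[j] for j in range(n)] for i in range(n)
    ]
    for i in range(n):
        for j in range(n):
            if not subset[i][j]:
                continue
            if any(subset[i][k] and subset[k][j] for k in range(n)):
                continue  # not a covering pair
            lattice.edges.add((i, j))
            lattice.children.setdefault(i, []).append(j)
            lattice.parents.setdefault(j, []).append(i)
    for adj in (lattice.children, lattice.parents):
        for key in adj:
            adj[key].sort(key=lambda idx: ordered[idx].sort_key())
    return lattice


def concepts_of(context: FormalContext) -> ConceptLattice:
    """Convenience: enumerate concepts and build the lattice in one call."""
    return build_lattice(enumerate_concepts(context))
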