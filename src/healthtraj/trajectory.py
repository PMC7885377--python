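"""Health trajectories and the clinical decision-making (what-if) layer.

A health trajectory is a chain of concepts walking down the lattice: each
step follows a covering edge (adds the factors closing one more step), the
patient set shrinks, and the smoothed reoperation risk strictly decreases.
The what-if layer places a patient at the most specific concept whose
intent is the closure of their positive factors, ranks the covering moves
out of it, and quantifies the effect of adding or removing factors.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._util import HealthTrajError
from .cohort import FactorVector
from .fca import Concept, ConceptLattice
from .risk import ConceptRisk, RiskTable, edge_reduction

#: Absolute tolerance distinguishing "strictly lower risk" from a float tie.
RISK_TIE_TOL = 1e-12


class TrajectoryError(HealthTrajError):
    """Invalid trajectory or what-if query."""


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Placement:
    """Where a factor set lands in the lattice.

    ``in_data`` is False when the closed concept has an empty extent, i.e. no
    registered patient carries this factor combination; the risk is then
    unavailable and downstream reports say "no data" instead of extrapolating.
    """

    concept: Concept
    risk: ConceptRisk | None
    in_data: bool


def place_patient(
    lattice: ConceptLattice,
    risks: RiskTable,
    patient: FactorVector | Iterable[str],
) -> Placement:
    """Most specific concept containing the patient: intent = closure(factors).

    Closed intents are intersection-closed, so the minimal closed superset of
    the patient's factors is found by intersecting over all concept intents
    that contain them (equivalently: the candidate with the smallest intent).
    """
    factors = frozenset(patient.factors if isinstance(patient, FactorVector) else patient)
    candidates = [c for c in lattice.concepts if factors <= c.intent]
    if not candidates:  # cannot happen for a complete lattice over these attributes
        raise TrajectoryError(f"factors {sorted(factors)} outside the attribute universe")
    concept = min(candidates, key=Concept.sort_key)
    risk = risks.get(concept)
    return Placement(concept=concept, risk=risk, in_data=risk is not None)


# ---------------------------------------------------------------------------
# Candidate moves (covering successors)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateMove:
    """One covering step out of a concept."""

    added_factors: frozenset[str]
    target: Concept
    target_risk: ConceptRisk
    change_pct: int  # positive = reduction, negative = deterioration
    reliability: str

    @property
    def improving(self) -> bool:
        return self.change_pct > 0


def _edge_label(p_from: float, p_to: float) -> int:
    # A stratum with zero events makes every smoothed risk zero; report a
    # flat 0% change instead of failing on the undefined relative change.
    if p_from == 0 and p_to == 0:
        return 0
    return edge_reduction(p_from, p_to)


def successors(
    lattice: ConceptLattice, risks: RiskTable, concept: Concept
) -> list[CandidateMove]:
    """Covering children with data, labelled and ranked.

    Sorted by reduction (descending), then child size (descending), then
    intent lexicographically — the order a decision tool presents options in.
    """
    base = risks.get(concept)
    if base is None:
        return []
    moves = []
    for child in lattice.child_concepts(concept):
        child_risk = risks.get(child)
        if child_risk is None:
            continue
        moves.append(
            CandidateMove(
                added_factors=child.intent - concept.intent,
                target=child,
                target_risk=child_risk,
                change_pct=_edge_label(base.p_adj, child_risk.p_adj),
                reliability=child_risk.reliability,
            )
        )
    moves.sort(
        key=lambda m: (-m.change_pct, -m.target_risk.n, tuple(sorted(m.target.intent)))
    )
    return moves


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Trajectory:
    """A chain of concepts with growing intents and strictly decreasing risk.

    ``added_factors`` and ``reductions`` describe the steps (length =
    len(steps) - 1); ``risks`` holds the smoothed risk at every concept.
    """

    steps: tuple[Concept, ...]
    added_factors: tuple[frozenset[str], ...]
    risks: tuple[float, ...]
    reductions: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def final_risk(self) -> float:
        return self.risks[-1]

    def validate(self) -> None:
        """Assert the defining invariants (nesting + strict risk decrease)."""
        for a, b in zip(self.steps, self.steps[1:]):
            if not a.intent < b.intent:
                raise TrajectoryError("intents must be strictly nested increasing")
            if not b.extent <= a.extent:
                raise TrajectoryError("extents must be nested decreasing")
        for r1, r2 in zip(self.risks, self.risks[1:]):
            if not r2 < r1 - RISK_TIE_TOL:
                raise TrajectoryError("risk must strictly decrease along the trajectory")


def enumerate_trajectories(
    lattice: ConceptLattice,
    risks: RiskTable,
    start: Concept,
    max_len: int | None = None,
) -> list[Trajectory]:
    """All covering-edge chains from ``start`` with strictly decreasing risk.

    ``max_len`` caps the number of steps (edges); the default is the number
    of attributes, the most factors any chain can add.  The singleton chain
    is always included, so the result is closed under prefixes.  Output is
    deterministic: final risk ascending, then length, then the intent
    sequence.
    """
    base = risks.get(start)
    if base is None:
        return []
    if max_len is None:
        max_len = len(lattice.bottom.intent) or 1

    out: list[Trajectory] = []

    def rec(path: list[Concept], path_risks: list[float], labels: list[int]) -> None:
        added = tuple(
            b.intent - a.intent for a, b in zip(path, path[1:])
        )
        out.append(
            Trajectory(tuple(path), added, tuple(path_risks), tuple(labels))
        )
        if len(path) - 1 >= max_len:
            return
        for child in lattice.child_concepts(path[-1]):
            risk = risks.get(child)
            if risk is None:
                continue
            if risk.p_adj < path_risks[-1] - RISK_TIE_TOL:
                rec(
                    path + [child],
                    path_risks + [risk.p_adj],
                    labels + [_edge_label(path_risks[-1], risk.p_adj)],
                )

    rec([start], [base.p_adj], [])
    out.sort(
        key=lambda t: (
            t.final_risk,
            len(t),
            tuple(tuple(sorted(c.intent)) for c in t.steps),
        )
    )
    return out


# ---------------------------------------------------------------------------
# What-if reports
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WhatIfReport:
    """CDMT answer: stratum rate, current placement, effect of a change.

    When ``add``/``remove`` are empty the report is exploratory and
    ``candidates`` ranks all covering moves out of the baseline concept.
    ``chained_steps`` decomposes a multi-factor improvement into covering
    steps when the target sits below the baseline in the lattice.
    """

    stratum_rate: float
    stratum_size: int
    baseline: Placement
    add: frozenset[str]
    remove: frozenset[str]
    target: Placement | None
    change_pct: int | None  # positive = reduction, negative = deterioration
    no_data: bool
    candidates: tuple[CandidateMove, ...] = ()
    chained_steps: tuple[CandidateMove, ...] = ()

    def to_dict(self) -> dict:
        def move(m: CandidateMove) -> dict:
            return {
                "added_factors": sorted(m.added_factors),
                "target_intent": sorted(m.target.intent),
                "target_n": m.target_risk.n,
                "target_p_adj": m.target_risk.p_adj,
                "change_pct": m.change_pct,
                "reliability": m.reliability,
            }

        def placement(p: Placement | None) -> dict | None:
            if p is None:
                return None
            return {
                "intent": sorted(p.concept.intent),
                "n": p.risk.n if p.risk else 0,
                "p_adj": p.risk.p_adj if p.risk else None,
                "reliability": p.risk.reliability if p.risk else None,
                "in_data": p.in_data,
            }

        return {
            "stratum_rate": self.stratum_rate,
            "stratum_size": self.stratum_size,
            "baseline": placement(self.baseline),
            "add": sorted(self.add),
            "remove": sorted(self.remove),
            "target": placement(self.target),
            "change_pct": self.change_pct,
            "no_data": self.no_data,
            "candidates": [move(m) for m in self.candidates],
            "chained_steps": [move(m) for m in self.chained_steps],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def _covering_path(
    lattice: ConceptLattice, risks: RiskTable, source: Concept, target: Concept
) -> tuple[CandidateMove, ...]:
    """One shortest covering-edge path source -> target through ranked concepts."""
    if not source.intent < target.intent:
        return ()
    prev: dict[frozenset, Concept] = {}
    queue = deque([source])
    seen = {source.intent}
    while queue:
        node = queue.popleft()
        if node.intent == target.intent:
            break
        for child in lattice.child_concepts(node):
            if child.intent in seen or risks.get(child) is None:
                continue
            if not child.intent <= target.intent:
                continue
            seen.add(child.intent)
            prev[child.intent] = node
            queue.append(child)
    if target.intent not in prev:
        return ()
    chain = [target]
    while chain[-1].intent != source.intent:
        chain.append(prev[chain[-1].intent])
    chain.reverse()
    steps = []
    for a, b in zip(chain, chain[1:]):
        risk_a, risk_b = risks[a], risks[b]
        steps.append(
            CandidateMove(
                added_factors=b.intent - a.intent,
                target=b,
                target_risk=risk_b,
                change_pct=_edge_label(risk_a.p_adj, risk_b.p_adj),
                reliability=risk_b.reliability,
            )
        )
    return tuple(steps)


def what_if(
    lattice: ConceptLattice,
    risks: RiskTable,
    patient: FactorVector | Iterable[str],
    add: Iterable[str] = (),
    remove: Iterable[str] = (),
) -> WhatIfReport:
    """Quantify the risk change when a patient adds/removes positive factors.

    Removing a protective factor is adding a negative one: the report signs
    the change accordingly (positive percent = reduction).  A modified factor
    set that closes to an empty-extent concept yields ``no_data`` — the
    method is empirical and does not extrapolate beyond observed groups.
    """
    factors = frozenset(patient.factors if isinstance(patient, FactorVector) else patient)
    add = frozenset(add)
    remove = frozenset(remove)
    if add & remove:
        raise TrajectoryError("add and remove sets must be disjoint")
    missing = remove - factors
    if missing:
        raise TrajectoryError(
            f"cannot remove factor(s) not present: {sorted(missing)}"
        )
    already = add & factors
    if already:
        raise TrajectoryError(f"factor(s) already present: {sorted(already)}")

    baseline = place_patient(lattice, risks, factors)

    if not add and not remove:
        candidates = (
            tuple(successors(lattice, risks, baseline.concept))
            if baseline.in_data
            else ()
        )
        return WhatIfReport(
            stratum_rate=risks.p_total,
            stratum_size=risks.stratum_size,
            baseline=baseline,
            add=add,
            remove=remove,
            target=None,
            change_pct=None,
            no_data=not baseline.in_data,
            candidates=candidates,
        )

    target = place_patient(lattice, risks, (factors - remove) | add)
    no_data = not (baseline.in_data and target.in_data)
    change = None
    chained: tuple[CandidateMove, ...] = ()
    if not no_data:
        change = _edge_label(baseline.risk.p_adj, target.risk.p_adj)
        chained = _covering_path(lattice, risks, baseline.concept, target.concept)
    direct = (
        (
            CandidateMove(
                added_factors=target.concept.intent - baseline.concept.intent,
                target=target.concept,
                target_risk=target.risk,
                change_pct=change,
                reliability=target.risk.reliability,
            ),
        )
        if not no_data
        else ()
    )
    return WhatIfReport(
        stratum_rate=risks.p_total,
        stratum_size=risks.stratum_size,
        baseline=baseline,
        add=add,
        remove=remove,
        target=target,
        change_pct=change,
        no_data=no_data,
        candidates=direct,
        chained_steps=chained,
    )


def render_report(report: WhatIfReport, stratum_label: str = "stratum") -> str:
    """Human-readable three-step rendering of a what-if report.

    Step 1: the overall rate in the patient's sex/age group; step 2: the rate
    in the patient's current factor group; step 3: the modified group(s).
    """

    def pct(p: float) -> str:
        return f"{100 * p:.2f}%"

    def intent_label(concept: Concept) -> str:
        return ", ".join(sorted(concept.intent)) if concept.intent else "NO COMMON FACTORS"

    lines = [
        f"Step 1 — group rate: {stratum_label}, N = {report.stratum_size}, "
        f"reoperation rate {pct(report.stratum_rate)}",
    ]
    b = report.baseline
    if b.in_data:
        lines.append(
            f"Step 2 — current factors [{intent_label(b.concept)}]: "
            f"n = {b.risk.n} ({100 * b.risk.share:.1f}% of group), "
            f"risk {pct(b.risk.p_adj)} [{b.risk.reliability}]"
        )
    else:
        lines.append(
            f"Step 2 — current factors [{intent_label(b.concept)}]: "
            "no data for this combination"
        )
    if report.target is not None:
        t = report.target
        changed = []
        if report.add:
            changed.append("add " + ", ".join(sorted(report.add)))
        if report.remove:
            changed.append("remove " + ", ".join(sorted(report.remove)))
        header = f"Step 3 — after {'; '.join(changed)}"
        if report.no_data:
            lines.append(f"{header}: no data for this combination")
        else:
            direction = "reduction" if report.change_pct >= 0 else "deterioration"
            lines.append(
                f"{header}: group [{intent_label(t.concept)}], n = {t.risk.n}, "
                f"risk {pct(t.risk.p_adj)} ({direction} of {abs(report.change_pct)}%) "
                f"[{t.risk.reliability}]"
            )
            for step in report.chained_steps:
                direction = "reduction" if step.change_pct >= 0 else "deterioration"
                lines.append(
                    f"    step: +{', '.join(sorted(step.added_factors))} -> "
                    f"risk {pct(step.target_risk.p_adj)} "
                    f"({direction} of {abs(step.change_pct)}%)"
                )
    elif report.candidates:
        lines.append("Step 3 — candidate single moves:")
        for m in report.candidates:
            direction = "reduction" if m.change_pct >= 0 else "deterioration"
            lines.append(
                f"    +{', '.join(sorted(m.added_factors))}: "
                f"risk {pct(m.target_risk.p_adj)}, n = {m.target_risk.n} "
                f"({direction} of {abs(m.change_pct)}%) [{m.reliability}]"
            )
    return "\n".join(lines)
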