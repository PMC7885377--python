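"""Per-concept reoperation risk: empirical proportions, shrinkage smoothing,
edge-reduction labels and reliability classes.

Small concepts can have zero observed events, making the raw proportion an
unusable risk estimate.  Each concept's proportion is therefore shrunk
toward the whole-stratum rate with a pseudo-count mass ``m``:

    p_adj = (k + m * p_total) / (n + m)

equivalent to the posterior mean under a Beta(m*p_total, m*(1 - p_total))
prior.  The whole-stratum concept is a fixed point (its rate is unchanged),
above-average groups are pulled down, below-average groups (including
zero-event groups) are pulled up — exactly the behaviour the trajectory
semantics require.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from ._util import HealthTrajError, round_half_away
from .fca import Concept, ConceptLattice, FormalContext


class RiskError(HealthTrajError):
    """Invalid risk computation input."""


@dataclass(frozen=True)
class SmoothingConfig:
    """Shrinkage configuration.

    m:
        Pseudo-count mass (> 0); larger values pull small groups harder
        toward the stratum rate.  Default 10 — roughly the size below which
        a concept's raw proportion is dominated by the prior.
    p_total:
        Stratum-level event proportion; if ``None`` it is computed from the
        context when the risk table is built.
    """

    m: float = 10.0
    p_total: float | None = None

    def __post_init__(self) -> None:
        if not self.m > 0:
            raise ValueError("pseudo-count mass m must be positive")
        if self.p_total is not None and not 0.0 <= self.p_total <= 1.0:
            raise ValueError("p_total must be a proportion in [0, 1]")


@dataclass(frozen=True)
class ConceptRisk:
    """Risk annotation of one concept."""

    concept: Concept
    n: int
    k: int
    p_emp: float  # NaN when n == 0
    p_adj: float
    share: float  # n / stratum size
    reliability: str  # green | red | yellow


def empirical_risk(k: int, n: int) -> float:
    """Raw event proportion k/n; NaN marks the undefined n = 0 case."""
    if k < 0 or n < 0:
        raise RiskError("counts must be nonnegative")
    if k > n:
        raise RiskError(f"event count k={k} exceeds group size n={n}")
    if n == 0:
        return math.nan
    return k / n


def smoothed_risk(k: int, n: int, cfg: SmoothingConfig) -> float:
    """Pseudo-count shrinkage of k/n toward the stratum rate ``cfg.p_total``."""
    if cfg.p_total is None:
        raise RiskError("SmoothingConfig.p_total must be set for smoothed_risk")
    if k < 0 or n < 0 or k > n:
        raise RiskError(f"invalid counts k={k}, n={n}")
    # algebraically (k + m*p_total) / (n + m); this form makes the
    # whole-stratum fixed point (k = n*p_total -> p_adj = p_total) exact
    return cfg.p_total + (k - n * cfg.p_total) / (n + cfg.m)


def edge_reduction(p_from: float, p_to: float) -> int:
    """Signed integer percent change of risk along a lattice edge.

    Positive = reduction (p_to < p_from), negative = deterioration.  The
    larger of the two probabilities is the denominator in both directions,
    so adding and removing the same factor report the same magnitude.
    Rounding is half-away-from-zero to an integer.
    """
    if p_from < 0 or p_to < 0:
        raise RiskError("probabilities must be nonnegative")
    if p_from == 0 and p_to == 0:
        raise RiskError("relative change undefined: both probabilities are zero")
    pct = 100.0 * (p_from - p_to) / max(p_from, p_to)
    return int(round_half_away(pct, 0))


def classify_reliability(
    n: int, k: int, stratum_size: int, green_share: float = 0.10
) -> str:
    """Reliability colour of a concept's risk estimate.

    green  — the concept holds at least ``green_share`` of the stratum;
    red    — the raw proportion is zero (estimate driven by the prior alone);
    yellow — everything else.
    """
    if stratum_size <= 0:
        raise RiskError("stratum size must be positive")
    if n >= green_share * stratum_size:
        return "green"
    if n > 0 and k == 0:
        return "red"
    return "yellow"


class RiskTable:
    """Risk rows for every nonempty-extent concept of a lattice.

    Iterable in the deterministic (|intent|, intent) order; indexable by
    :class:`Concept`.
    """

    def __init__(self, rows: Sequence[ConceptRisk], p_total: float, stratum_size: int):
        self.rows = list(rows)
        self.p_total = p_total
        self.stratum_size = stratum_size
        self._by_intent = {r.concept.intent: r for r in self.rows}

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def __contains__(self, concept: Concept) -> bool:
        return concept.intent in self._by_intent

    def __getitem__(self, concept: Concept) -> ConceptRisk:
        return self._by_intent[concept.intent]

    def get(self, concept: Concept) -> ConceptRisk | None:
        return self._by_intent.get(concept.intent)

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: concept_id, intent, n, k, p_emp, p_adj, share, reliability."""
        return pd.DataFrame(
            {
                "concept_id": [f"c{i:03d}" for i in range(len(self.rows))],
                "intent": [";".join(sorted(r.concept.intent)) for r in self.rows],
                "n": [r.n for r in self.rows],
                "k": [r.k for r in self.rows],
                "p_emp": [r.p_emp for r in self.rows],
                "p_adj": [r.p_adj for r in self.rows],
                "share": [r.share for r in self.rows],
                "reliability": [r.reliability for r in self.rows],
            }
        )


def risk_table(
    lattice: ConceptLattice,
    context: FormalContext,
    cfg: SmoothingConfig | None = None,
    green_share: float = 0.10,
) -> RiskTable:
    """Annotate every nonempty-extent concept with counts and risks.

    Rows come out sorted by (|intent|, intent) because the lattice keeps its
    concepts in that order.  Empty-extent concepts (no denominator) carry no
    row; they stay in the lattice for structure but are unrankable.
    """
    cfg = cfg or SmoothingConfig()
    stratum_size = len(context.objects)
    p_total = cfg.p_total
    if p_total is None:
        p_total = float(context.outcome.mean()) if stratum_size else 0.0
        cfg = replace(cfg, p_total=p_total)

    object_index = {o: i for i, o in enumerate(context.objects)}
    rows = []
    for concept in lattice.concepts:
        n = len(concept.extent)
        if n == 0:
            continue
        k = int(context.outcome[[object_index[o] for o in concept.extent]].sum())
        rows.append(
            ConceptRisk(
                concept=concept,
                n=n,
                k=k,
                p_emp=empirical_risk(k, n),
                p_adj=smoothed_risk(k, n, cfg),
                share=n / stratum_size,
                reliability=classify_reliability(n, k, stratum_size, green_share),
            )
        )
    return RiskTable(rows, p_total=p_total, stratum_size=stratum_size)
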