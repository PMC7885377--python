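import numpy as np
import pytest

from healthtraj import (
    FactorVector,
    build_context,
    concepts_of,
    edge_reduction,
    enumerate_trajectories,
    place_patient,
    render_report,
    risk_table,
    successors,
    what_if,
)
from healthtraj.trajectory import TrajectoryError

from .oracles import brute_trajectories, random_context


def pipeline(vectors, universe):
    ctx = build_context(vectors, universe)
    lattice = concepts_of(ctx)
    return ctx, lattice, risk_table(lattice, ctx)


@pytest.fixture()
def three_ways():
    """A stratum built to have exactly three improving single-factor moves
    from the no-factor group (and one non-improving one), mirroring the
    case-study structure."""
    vectors = []
    idx = 0

    def add(n_total, n_events, factors):
        nonlocal idx
        for i in range(n_total):
            vectors.append(
                FactorVector(f"p{idx}", frozenset(factors), i < n_events)
            )
            idx += 1

    add(40, 8, [])                     # high-risk base group
    add(30, 1, ["Sport"])              # strong improvement
    add(30, 2, ["LongDistWalk"])       # medium improvement
    add(30, 3, ["Activity"])           # mild improvement
    add(30, 8, ["NoSmoking"])          # deterioration
    return pipeline(vectors, ["Activity", "LongDistWalk", "NoSmoking", "Sport"])


class TestPlacement:
    def test_no_factors_lands_at_top(self, older_female):
        placement = place_patient(older_female.lattice, older_female.risks, [])
        assert placement.concept == older_female.lattice.top
        assert placement.in_data

    def test_case_a_like_patient_lands_in_no_smoking_group(self, older_female):
        placement = place_patient(
            older_female.lattice, older_female.risks, ["NoSmoking"]
        )
        assert "NoSmoking" in placement.concept.intent

    def test_full_factor_set_lands_at_minimal_superset_concept(self, older_female):
        factors = frozenset(
            {"NoSmoking", "lowBMI", "Activity", "Sport", "LongDistWalk"}
        )
        placement = place_patient(older_female.lattice, older_female.risks, factors)
        # brute scan: smallest-intent concept whose intent contains all factors
        candidates = [
            c for c in older_female.lattice.concepts if factors <= c.intent
        ]
        expected = min(candidates, key=lambda c: (len(c.intent), sorted(c.intent)))
        assert placement.concept == expected

    def test_placement_is_idempotent(self, older_female):
        for concept in older_female.lattice.concepts:
            if concept.extent:
                again = place_patient(
                    older_female.lattice, older_female.risks, concept.intent
                )
                assert again.concept == concept

    def test_unseen_combination_flags_no_data(self):
        vectors = [
            FactorVector("p1", frozenset({"A"}), False),
            FactorVector("p2", frozenset({"B"}), True),
        ]
        _, lattice, risks = pipeline(vectors, ["A", "B"])
        placement = place_patient(lattice, risks, {"A", "B"})
        assert not placement.in_data
        assert placement.risk is None


class TestSuccessors:
    def test_three_improving_moves_ranked_by_reduction(self, three_ways):
        _, lattice, risks = three_ways
        moves = successors(lattice, risks, lattice.top)
        improving = [m for m in moves if m.improving]
        assert len(improving) == 3
        assert [sorted(m.added_factors)[0] for m in improving] == [
            "Sport",
            "LongDistWalk",
            "Activity",
        ]
        assert all(
            a.change_pct >= b.change_pct for a, b in zip(moves, moves[1:])
        )

    def test_deteriorations_still_reported(self, three_ways):
        _, lattice, risks = three_ways
        moves = successors(lattice, risks, lattice.top)
        worse = [m for m in moves if m.change_pct < 0]
        assert worse and sorted(worse[0].added_factors) == ["NoSmoking"]

    def test_labels_match_edge_reduction(self, older_female):
        lattice, risks = older_female.lattice, older_female.risks
        for move in successors(lattice, risks, lattice.top):
            expected = edge_reduction(
                risks[lattice.top].p_adj, move.target_risk.p_adj
            )
            assert move.change_pct == expected

    def test_empty_extent_concept_has_no_moves(self):
        vectors = [
            FactorVector("p1", frozenset({"A"}), False),
            FactorVector("p2", frozenset({"B"}), True),
        ]
        _, lattice, risks = pipeline(vectors, ["A", "B"])
        assert successors(lattice, risks, lattice.bottom) == []


class TestTrajectories:
    def test_bottom_concept_yields_only_itself(self):
        vectors = [
            FactorVector("p0", frozenset(), True),
            FactorVector("p1", frozenset({"A"}), False),
            FactorVector("p2", frozenset({"A", "B"}), False),
        ]
        _, lattice, risks = pipeline(vectors, ["A", "B"])
        assert lattice.bottom.extent  # the most specific group is observed
        trajs = enumerate_trajectories(lattice, risks, lattice.bottom)
        assert len(trajs) == 1 and len(trajs[0]) == 1

    def test_all_trajectories_satisfy_invariants(self, older_female):
        lattice, risks = older_female.lattice, older_female.risks
        trajs = enumerate_trajectories(lattice, risks, lattice.top)
        assert trajs
        for t in trajs:
            t.validate()
            assert len(t.added_factors) == len(t) - 1
            assert len(t.reductions) == len(t) - 1

    def test_prefix_closure(self, older_female):
        lattice, risks = older_female.lattice, older_female.risks
        trajs = enumerate_trajectories(lattice, risks, lattice.top)
        seqs = {tuple(c.intent for c in t.steps) for t in trajs}
        for seq in seqs:
            for cut in range(1, len(seq)):
                assert seq[:cut] in seqs

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_dfs(self, seed):
        ctx = random_context(np.random.default_rng(seed), 10, 4, event_rate=0.3)
        lattice = concepts_of(ctx)
        risks = risk_table(lattice, ctx)
        risk_map = {r.concept.intent: r.p_adj for r in risks}
        ours = enumerate_trajectories(lattice, risks, lattice.top, max_len=4)
        mine = {tuple(c.intent for c in t.steps) for t in ours}
        oracle = brute_trajectories(lattice.concepts, risk_map, lattice.top, 4)
        assert mine == oracle

    def test_max_len_caps_steps(self, older_female):
        lattice, risks = older_female.lattice, older_female.risks
        trajs = enumerate_trajectories(lattice, risks, lattice.top, max_len=1)
        assert max(len(t) for t in trajs) <= 2

    def test_deterministic_order(self, older_female):
        lattice, risks = older_female.lattice, older_female.risks
        a = enumerate_trajectories(lattice, risks, lattice.top)
        b = enumerate_trajectories(lattice, risks, lattice.top)
        assert a == b
        finals = [t.final_risk for t in a]
        assert finals == sorted(finals)


class TestWhatIf:
    def test_add_then_remove_is_net_zero(self, older_female):
        lattice, risks = older_female.lattice, older_female.risks
        patient = frozenset({"NoSmoking"})
        forward = what_if(lattice, risks, patient, add={"Activity"})
        back = what_if(
            lattice, risks, patient | {"Activity"}, remove={"Activity"}
        )
        assert back.target.concept == forward.baseline.concept
        assert back.change_pct == -forward.change_pct

    def test_removing_a_protective_factor_is_a_deterioration(self, older_female):
        lattice, risks = older_female.lattice, older_female.risks
        report = what_if(lattice, risks, {"NoSmoking"}, remove={"NoSmoking"})
        assert report.change_pct is not None and report.change_pct < 0
        # magnitude equals the printed-convention label of the two risks
        assert report.change_pct == edge_reduction(
            report.baseline.risk.p_adj, report.target.risk.p_adj
        )

    def test_adding_improving_factor_reports_edge_reduction(self, older_female):
        lattice, risks = older_female.lattice, older_female.risks
        report = what_if(lattice, risks, {"NoSmoking"}, add={"Activity"})
        assert report.change_pct == edge_reduction(
            report.baseline.risk.p_adj, report.target.risk.p_adj
        )

    def test_removing_absent_factor_rejected(self, older_female):
        with pytest.raises(TrajectoryError, match="not present"):
            what_if(
                older_female.lattice, older_female.risks, set(), remove={"NoSmoking"}
            )

    def test_unseen_target_reports_no_data(self):
        vectors = [
            FactorVector("p1", frozenset({"A"}), False),
            FactorVector("p2", frozenset({"B"}), True),
        ]
        _, lattice, risks = pipeline(vectors, ["A", "B"])
        report = what_if(lattice, risks, {"A"}, add={"B"})
        assert report.no_data
        assert report.change_pct is None
        assert "no data" in render_report(report)

    def test_exploratory_report_ranks_candidates(self, three_ways):
        _, lattice, risks = three_ways
        report = what_if(lattice, risks, set())
        assert len(report.candidates) == 4
        text = render_report(report, "test-stratum")
        assert "Step 1" in text and "Step 2" in text and "Step 3" in text

    def test_chained_steps_decompose_multi_factor_moves(self, older_female):
        lattice, risks = older_female.lattice, older_female.risks
        report = what_if(
            lattice, risks, frozenset({"NoSmoking"}), add={"Activity", "lowBMI"}
        )
        if not report.no_data and report.chained_steps:
            added = frozenset().union(
                *(s.added_factors for s in report.chained_steps)
            )
            assert added == {"Activity", "lowBMI"}

    def test_report_json_round_trips(self, older_female):
        import json

        report = what_if(
            older_female.lattice, older_female.risks, {"NoSmoking"}, add={"Activity"}
        )
        doc = json.loads(report.to_json())
        assert doc["change_pct"] == report.change_pct
        assert doc["baseline"]["intent"] == ["NoSmoking"]
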