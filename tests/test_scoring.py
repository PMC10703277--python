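import numpy as np
import pytest
from scipy import stats

from meritrank.elicitation import enumerate_tasks, run_session
from meritrank.io import load_reference_weights
from meritrank.scoring import (
    ProposalRating,
    ScoredProposal,
    merit_cost_ratio,
    one_way_anova,
    rank_proposals,
    score_proposal,
    score_proposals,
    summarize_groups,
)
from meritrank.simulate import make_responder, sample_respondent
from meritrank.valuation import derive_point_values, interpolate_levels


@pytest.fixture(scope="module")
def reference():
    return load_reference_weights()


def rate(fw, **levels):
    base = {c.name: 1 for c in fw.criteria}
    base.update(levels)
    return ProposalRating("p", base)


class TestScoreProposal:
    def test_single_criterion_worked_examples(self, fw, reference):
        assert score_proposal(reference, rate(fw, Appropriateness=5)) == pytest.approx(29.3)
        assert score_proposal(reference, rate(fw, Significance=3)) == pytest.approx(16.8)

    def test_all_lowest_scores_zero(self, fw, reference):
        assert score_proposal(reference, rate(fw)) == 0.0

    def test_mixed_rating_hand_sum(self, fw, reference):
        # Medium Appropriateness + High Significance + Medium-low Relevance
        # + Medium-high Feasibility: 18.7 + 26.6 + 8.8 + 16.9
        rating = rate(fw, Appropriateness=3, Significance=5, Relevance=2, Feasibility=4)
        assert score_proposal(reference, rating) == pytest.approx(71.0)

    def test_additivity_across_criteria(self, fw, reference):
        rating = rate(fw, Appropriateness=4, Relevance=3)
        parts = sum(
            score_proposal(reference, rate(fw, **{c: r}))
            for c, r in [("Appropriateness", 4), ("Relevance", 3)]
        )
        assert score_proposal(reference, rating) == pytest.approx(parts)

    def test_missing_and_unknown_criteria_raise(self, fw, reference):
        with pytest.raises(ValueError, match="missing"):
            score_proposal(reference, ProposalRating("p", {"Appropriateness": 5}))
        bad = {c.name: 1 for c in fw.criteria} | {"Novelty": 3}
        with pytest.raises(ValueError, match="unknown"):
            score_proposal(reference, ProposalRating("p", bad))

    def test_derived_system_bounds_and_monotonicity(self, fw):
        model = sample_respondent(fw, seed=4)
        session = run_session(fw, make_responder(model))
        by_id = {t.task_id: t for t in enumerate_tasks(fw)}
        ps = interpolate_levels(
            derive_point_values(
                fw, [(by_id[r.task_id], r.answer) for r in session.answered_responses]
            ),
            fw,
        )
        assert score_proposal(ps, rate(fw)) == 0.0
        top = rate(fw, **{c.name: 5 for c in fw.criteria})
        assert score_proposal(ps, top) == pytest.approx(100.0, abs=1e-6)
        # raising any single criterion's level never lowers the total
        for c in fw.criteria:
            scores = [score_proposal(ps, rate(fw, **{c.name: r})) for r in range(1, 6)]
            assert all(b >= a for a, b in zip(scores, scores[1:]))


class TestRanking:
    def test_competition_tie_rule(self):
        scored = [
            ScoredProposal("a", 80.0),
            ScoredProposal("b", 60.0),
            ScoredProposal("c", 60.0),
        ]
        ranked = rank_proposals(scored)
        assert [(s.proposal_id, s.rank) for s in ranked] == [
            ("a", 1), ("b", 2), ("c", 2),
        ]

    def test_single_proposal(self):
        assert rank_proposals([ScoredProposal("only", 42.0)])[0].rank == 1

    def test_rank_invariant_under_input_order(self):
        rng = np.random.default_rng(0)
        scores = rng.permutation(101)[:20].astype(float)
        base = [ScoredProposal(f"p{i:02d}", s) for i, s in enumerate(scores)]
        expect = {
            s.proposal_id: 1 + sum(o.total_score > s.total_score for o in base)
            for s in base
        }
        for perm_seed in range(3):
            perm = np.random.default_rng(perm_seed).permutation(len(base))
            ranked = rank_proposals(
                [ScoredProposal(base[i].proposal_id, base[i].total_score) for i in perm]
            )
            assert {s.proposal_id: s.rank for s in ranked} == expect


class TestMeritCost:
    @pytest.mark.parametrize(
        "score,cost,expected", [(100.0, 2.0, 50.0), (0.0, 5.0, 0.0), (71.0, 1.0, 71.0)]
    )
    def test_ratio(self, score, cost, expected):
        assert merit_cost_ratio(score, cost) == expected

    @pytest.mark.parametrize("cost", [0.0, -1.0, None])
    def test_invalid_cost(self, cost):
        with pytest.raises(ValueError):
            merit_cost_ratio(50.0, cost)

    def test_score_proposals_table(self, fw, reference):
        ratings = [
            ProposalRating("hi", {c.name: 5 for c in fw.criteria}, cost=2.0),
            ProposalRating("lo", {c.name: 1 for c in fw.criteria}, cost=1.0),
            ProposalRating("nc", {c.name: 3 for c in fw.criteria}),
        ]
        out = score_proposals(reference, ratings)
        assert list(out["proposal_id"]) == ["hi", "nc", "lo"]
        assert out.loc[out["proposal_id"] == "hi", "merit_cost_ratio"].item() == (
            pytest.approx(100.1 / 2)
        )
        assert np.isnan(
            out.loc[out["proposal_id"] == "nc", "merit_cost_ratio"].item()
        )


class TestAnova:
    def test_hand_computed_example(self):
        res = one_way_anova([[1, 2, 3], [2, 3, 4]])
        assert res.F == pytest.approx(1.5)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_equal_means_nonzero_spread(self):
        res = one_way_anova([[1, 3], [0, 4]])
        assert res.F == 0.0
        assert res.p == 1.0

    def test_all_identical(self):
        res = one_way_anova([[2, 2], [2, 2, 2]])
        assert (res.F, res.p) == (0.0, 1.0)

    def test_zero_within_variance_unequal_means(self):
        res = one_way_anova([[1, 1], [2, 2]])
        assert np.isinf(res.F)
        assert res.p == 0.0

    def test_two_groups_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 9)
        res = one_way_anova([a, b])
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert res.F == pytest.approx(t**2, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            groups = [rng.normal(rng.normal(), 1.0, int(rng.integers(2, 12))) for _ in range(k)]
            res = one_way_anova(groups)
            ref = stats.f_oneway(*groups)
            assert res.F == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    @pytest.mark.parametrize("groups", [[[1, 2]], [[1], [2]], [[1], [2], [3]]])
    def test_degenerate_inputs_raise(self, groups):
        with pytest.raises(ValueError):
            one_way_anova(groups)


class TestSummarizeGroups:
    def _systems(self, fw, offsets, n, seed):
        systems, groups = [], []
        for gi, (name, mean_top) in enumerate(offsets.items()):
            for i in range(n):
                systems.append(
                    sample_respondent(
                        fw, seed=np.random.SeedSequence([seed, gi, i]),
                        mean_top=mean_top, concentration=40.0,
                    ).true_system
                )
                groups.append(name)
        return systems, groups

    def test_one_p_value_per_criterion(self, fw):
        systems, groups = self._systems(
            fw, {"consumer": [25, 25, 28, 22], "researcher": [25, 25, 25, 25]}, 20, 0
        )
        summary = summarize_groups(systems, groups, fw)
        assert list(summary.anova["criterion"]) == fw.criterion_names
        assert ((summary.anova["p"] >= 0) & (summary.anova["p"] <= 1)).all()
        assert set(summary.weights["group"]) == {"consumer", "researcher", "all"}

    def test_identical_groups_f_zero(self, fw):
        systems, _ = self._systems(fw, {"g": [25, 25, 25, 25]}, 4, 3)
        summary = summarize_groups(systems + systems, ["a"] * 4 + ["b"] * 4, fw)
        assert summary.anova["F"].abs().max() == pytest.approx(0.0, abs=1e-12)
        assert summary.anova["p"].min() == pytest.approx(1.0, abs=1e-12)

    def test_single_group_rejected(self, fw):
        systems, groups = self._systems(fw, {"g": [25, 25, 25, 25]}, 3, 5)
        with pytest.raises(ValueError):
            summarize_groups(systems, groups, fw)
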