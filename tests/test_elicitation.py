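import copy
import itertools

import numpy as np
import pytest

from meritrank.elicitation import (
    AlreadyResolvedError,
    PreferenceState,
    ResponderAborted,
    Response,
    Session,
    apply_inclusion_filters,
    enumerate_tasks,
    flag_speeder,
    next_task,
    run_session,
    session_completed,
)
from meritrank.simulate import make_responder, sample_respondent


def find_task(tasks, profile_x, profile_y):
    """The enumerated task comparing two profiles (either orientation);
    returns (task, answer-meaning-'x preferred')."""
    for t in tasks:
        a = set(t.option_a.assignments)
        b = set(t.option_b.assignments)
        if a == set(profile_x) and b == set(profile_y):
            return t, "A"
        if a == set(profile_y) and b == set(profile_x):
            return t, "B"
    raise AssertionError(f"no task for {profile_x} vs {profile_y}")


class TestEnumerate:
    def test_counts_against_brute_force(self, fw):
        tasks = enumerate_tasks(fw)
        assert len(tasks) == 54  # C(4,2) * C(3,2)^2
        # independent brute force: all profile pairs on each criteria pair,
        # keep strict trade-offs, one per unordered pair
        names = [c.name for c in fw.criteria]
        expected = set()
        for c1, c2 in itertools.combinations(sorted(names), 2):
            e1 = fw.criterion(c1).elicited_ranks
            e2 = fw.criterion(c2).elicited_ranks
            profiles = [((c1, r1), (c2, r2)) for r1 in e1 for r2 in e2]
            for p, q in itertools.combinations(profiles, 2):
                (x1, x2), (y1, y2) = (p[0][1], p[1][1]), (q[0][1], q[1][1])
                if (x1 - y1) * (x2 - y2) < 0:  # strict trade-off
                    expected.add(frozenset([p, q]))
        got = {
            frozenset([t.option_a.assignments, t.option_b.assignments])
            for t in tasks
        }
        assert got == expected

    def test_two_by_two_single_task(self, toy2):
        tasks = enumerate_tasks(toy2)
        assert len(tasks) == 1
        t = tasks[0]
        assert t.option_a.assignments == (("X", 2), ("Y", 1))
        assert t.option_b.assignments == (("X", 1), ("Y", 2))

    def test_canonical_orientation_and_no_dominance(self, fw):
        for t in enumerate_tasks(fw):
            (c1, a1), (c2, a2) = t.option_a.assignments
            b1, b2 = t.option_b.rank_on(c1), t.option_b.rank_on(c2)
            assert c1 < c2
            assert a1 > b1 and a2 < b2  # A better on first criterion only

    def test_deterministic_order(self, fw):
        assert [t.task_id for t in enumerate_tasks(fw)] == [
            t.task_id for t in enumerate_tasks(fw)
        ]


class TestImplication:
    def test_empty_state_everything_undecided(self, fw):
        state = PreferenceState(fw)
        for t in state.tasks[::9]:
            assert state.implied_ordering(t) == "UNDECIDED"
            assert state.implied_ordering(t, lp_only=True) == "UNDECIDED"

    def test_transitive_chain_same_pair(self, fw):
        # X=(App 5, Feas 1), Y=(App 3, Feas 3), Z=(App 1, Feas 5):
        # X > Y and Y > Z force X > Z by transitivity
        state = PreferenceState(fw)
        X = (("Appropriateness", 5), ("Feasibility", 1))
        Y = (("Appropriateness", 3), ("Feasibility", 3))
        Z = (("Appropriateness", 1), ("Feasibility", 5))
        t_xy, ans_xy = find_task(state.tasks, X, Y)
        t_yz, ans_yz = find_task(state.tasks, Y, Z)
        t_xz, ans_xz = find_task(state.tasks, X, Z)
        state.record_answer(t_xy, ans_xy)
        state.record_answer(t_yz, ans_yz)
        assert state.implied[t_xz.task_id] == ans_xz
        assert t_xz.task_id not in state.undecided

    def test_cross_pair_implication_lp_only(self, fw):
        # one step of Appropriateness beats the whole Feasibility range, and
        # one step of Feasibility beats the whole Relevance range; then that
        # Appropriateness step must beat the Relevance range too, which no
        # same-pair chain can deliver
        state = PreferenceState(fw)
        t1, ans1 = find_task(
            state.tasks,
            (("Appropriateness", 5), ("Feasibility", 1)),
            (("Appropriateness", 3), ("Feasibility", 5)),
        )
        t2, ans2 = find_task(
            state.tasks,
            (("Feasibility", 5), ("Relevance", 1)),
            (("Feasibility", 3), ("Relevance", 5)),
        )
        t3, ans3 = find_task(
            state.tasks,
            (("Appropriateness", 5), ("Relevance", 1)),
            (("Appropriateness", 3), ("Relevance", 5)),
        )
        state.record_answer(t1, ans1)
        assert state.graph_ordering(t3) == "UNDECIDED"
        state.record_answer(t2, ans2)
        # no answered task touches the (Appropriateness, Relevance) pair, so
        # no same-pair chain exists - only the LP arithmetic forces t3
        assert not any(
            state.by_id[tid].pair == t3.pair for tid in state.answered
        )
        assert t3.task_id in state.implied
        assert state.implied[t3.task_id] == ans3
        assert state.implied_ordering(t3, lp_only=True) == ans3

    def test_partition_preserved_through_session(self, fw):
        state = PreferenceState(fw)
        model = sample_respondent(fw, seed=7)
        responder = make_responder(model)
        all_ids = {t.task_id for t in state.tasks}
        while (task := next_task(state, strategy="sequential")) is not None:
            answer, _ = responder(task)
            state.record_answer(task, answer)
            assert (
                set(state.answered) | set(state.implied) | state.undecided == all_ids
            )
            assert not set(state.answered) & set(state.implied)
            assert not set(state.answered) & state.undecided
            assert not set(state.implied) & state.undecided
        assert not state.undecided

    def test_record_answer_on_resolved_task_raises(self, toy2):
        state = PreferenceState(toy2)
        t = state.tasks[0]
        state.record_answer(t, "A")
        with pytest.raises(AlreadyResolvedError):
            state.record_answer(t, "B")


class TestNextTask:
    def test_done_when_resolved(self, toy2):
        state = PreferenceState(toy2)
        state.record_answer(state.tasks[0], "A")
        assert next_task(state) is None

    def test_sequential_takes_first_canonical(self, fw):
        state = PreferenceState(fw)
        assert next_task(state, strategy="sequential") is state.tasks[0]

    def test_fresh_greedy_matches_lp_probe_maximum(self, fw):
        # worst-case elimination count of the greedy pick must equal the
        # brute-force maximum over all candidates, counted by the LP engine
        state = PreferenceState(fw)

        def lp_worst_case(task):
            gains = []
            for answer in ("A", "B"):
                probe = copy.deepcopy(state)
                probe.record_answer(task, answer)
                gains.append(len(probe.implied))
            return min(gains)

        chosen = next_task(state, strategy="greedy")
        scores = {t.task_id: lp_worst_case(t) for t in state.tasks}
        assert scores[chosen.task_id] == max(scores.values())


class TestSessions:
    def test_full_session_properties(self, fw):
        model = sample_respondent(fw, seed=3)
        session = run_session(fw, make_responder(model), strategy="greedy")
        assert session.completed
        assert 1 <= session.n_answered <= 54
        assert len(session.repeat_responses) == 2
        assert session.consistency_correct == 2  # deterministic answers repeat
        # repeats re-ask previously answered tasks: first and median-index
        answered_ids = [r.task_id for r in session.answered_responses]
        rep = [r.task_id for r in session.repeat_responses]
        assert rep[0] == answered_ids[0]
        assert rep[1] == answered_ids[(len(answered_ids) - 1) // 2]

    def test_aborting_responder_gives_partial_session(self, fw):
        model = sample_respondent(fw, seed=3)
        session = run_session(fw, make_responder(model, abort_after=2))
        assert not session.completed
        assert len(session.responses) == 2

    def test_session_completed_replay(self, fw):
        model = sample_respondent(fw, seed=11)
        session = run_session(fw, make_responder(model))
        assert session_completed(fw, session)
        truncated = Session(
            respondent_id="t",
            responses=session.answered_responses[:3],
        )
        assert not session_completed(fw, truncated)

    def test_greedy_burden_not_above_sequential(self, fw):
        # the adaptive point of greedy selection: over a seeded cohort its
        # mean question count does not exceed plain sequential order
        burdens = {"greedy": [], "sequential": []}
        for strategy in burdens:
            for seed in range(30):
                model = sample_respondent(fw, seed=seed)
                s = run_session(fw, make_responder(model), strategy=strategy)
                burdens[strategy].append(s.n_answered)
        assert np.mean(burdens["greedy"]) <= np.mean(burdens["sequential"])


def _session_with_rts(rts, completed=True, group="consumer", consistency=2):
    s = Session(respondent_id="s", group=group, completed=completed)
    s.consistency_correct = consistency
    s.responses = [
        Response(task_id="X:2v1|Y:1v2", answer="A", rt_seconds=rt, sequence_index=i + 1)
        for i, rt in enumerate(rts)
    ]
    return s


class TestQualityControl:
    @pytest.mark.parametrize(
        "rts,expected",
        [
            ([5, 6, 0.9, 7], True),  # one sub-second answer
            ([2.5, 2.5, 2.5], True),  # median below 3 s
            ([1.2, 5, 5, 5], False),  # min >= 1 s, median >= 3 s
            ([1.0, 5, 5], False),  # exactly 1 s is not "less than 1 s"
            ([5, 2.9, 5, 5], False),  # lower median of even count is 5
            ([5, 2.9, 2.9, 5], True),  # lower median of even count is 2.9
        ],
    )
    def test_speeder_rule(self, rts, expected):
        assert flag_speeder(_session_with_rts(rts)) is expected

    def test_speeder_needs_responses(self):
        with pytest.raises(ValueError):
            flag_speeder(_session_with_rts([]))

    def test_partition(self):
        sessions = [
            _session_with_rts([5, 6, 7], completed=True),
            _session_with_rts([0.5, 0.6, 0.5], completed=True),
            _session_with_rts([5, 6], completed=False),
        ]
        report = apply_inclusion_filters(sessions)
        assert len(report.included) == 1
        assert len(report.excluded_speeder) == 1
        assert len(report.non_completer) == 1

    def test_consistency_tally(self):
        sessions = [
            _session_with_rts([5] * 4, group="consumer", consistency=2),
            _session_with_rts([5] * 4, group="consumer", consistency=2),
            _session_with_rts([5] * 4, group="researcher", consistency=1),
        ]
        report = apply_inclusion_filters(sessions)
        tally = report.consistency_tally
        assert tally.loc["consumer", 2] == 2
        assert tally.loc["researcher", 1] == 1
        assert tally.to_numpy().sum() == 3

    def test_empty_input(self):
        report = apply_inclusion_filters([])
        assert report.included == []
        assert report.consistency_tally.empty
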