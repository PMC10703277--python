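"""Adaptive pairwise-ranking elicitation over two-criterion trade-off tasks.

The engine enumerates every choice task that pits two *partial profiles*
(hypothetical proposals described on just two criteria) against each other
with a strict trade-off, then runs an adaptive questioning loop: after each
answer, every still-open task whose ordering is now logically forced is
moved to the *implied* set and never asked.  Implication is decided by
linear-programming feasibility over additive level values — if "B
preferred" is infeasible given the answers so far, A is implied — which
subsumes plain transitivity chaining and also captures cross-pair
arithmetic consequences.  The questioning therefore ends with every
enumerated task pairwise ranked, explicitly or implicitly.

Two cheap sound shortcuts keep the number of LP solves small: a per
criteria-pair digraph (dominance plus recorded orderings, closed under
reachability) settles most same-pair implications combinatorially, and a
pool of feasible witness points proves most "still undecided" verdicts
without any solve.  Both shortcuts agree with the LP by construction.

Quality control mirrors the survey protocol: two answered tasks are
re-asked at the end of each session as a consistency check, and sessions
are flagged as "speeders" when any response took under 1 second or the
median response time is under 3 seconds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .framework import CriteriaFramework
from .valuation import FEAS_TOL, PROBE_MARGIN, TOTAL_POINTS, ConstraintSpace, InconsistencyError

__all__ = [
    "PartialProfile",
    "ChoiceTask",
    "Response",
    "Session",
    "PreferenceState",
    "ResponderAborted",
    "AlreadyResolvedError",
    "enumerate_tasks",
    "implied_ordering",
    "next_task",
    "record_answer",
    "run_session",
    "flag_speeder",
    "apply_inclusion_filters",
    "session_completed",
    "InclusionReport",
    "dominance_edges",
    "profile_key",
]

ANSWERS = ("A", "B", "EQUAL")

#: Default QC thresholds (seconds), exposed on the CLI.
MIN_RT_SECONDS = 1.0
MIN_MEDIAN_RT_SECONDS = 3.0


class ResponderAborted(Exception):
    """A responder stopped answering mid-session."""


class AlreadyResolvedError(ValueError):
    """An answer was recorded for a task that is no longer undecided."""


@dataclass(frozen=True)
class PartialProfile:
    """A hypothetical proposal described on exactly two criteria.

    ``assignments`` holds two ``(criterion name, level rank)`` pairs sorted
    by criterion name; levels are elicited levels of their criteria.
    """

    assignments: tuple[tuple[str, int], tuple[str, int]]

    def __post_init__(self):
        if len(self.assignments) != 2:
            raise ValueError("a partial profile assigns exactly two criteria")
        if self.assignments[0][0] >= self.assignments[1][0]:
            object.__setattr__(
                self, "assignments", tuple(sorted(self.assignments))
            )

    @property
    def criteria(self) -> tuple[str, str]:
        return self.assignments[0][0], self.assignments[1][0]

    def rank_on(self, criterion: str) -> int:
        for c, r in self.assignments:
            if c == criterion:
                return r
        raise KeyError(criterion)


def profile_key(profile: PartialProfile) -> tuple[int, int]:
    """Node key for the per-pair ordering graph: ranks in criterion-name order."""
    return profile.assignments[0][1], profile.assignments[1][1]


@dataclass(frozen=True)
class ChoiceTask:
    """A trade-off question: option_a beats option_b on the first criterion
    (lexicographically) and loses on the second — canonical orientation."""

    task_id: str
    option_a: PartialProfile
    option_b: PartialProfile

    @property
    def pair(self) -> frozenset[str]:
        return frozenset(self.option_a.criteria)


def _make_task(c1: str, a1: int, b1: int, c2: str, a2: int, b2: int) -> ChoiceTask:
    # c1 < c2 lexicographically; a1 > b1 (A better on c1), a2 < b2.
    tid = f"{c1}:{a1}v{b1}|{c2}:{a2}v{b2}"
    return ChoiceTask(
        task_id=tid,
        option_a=PartialProfile(((c1, a1), (c2, a2))),
        option_b=PartialProfile(((c1, b1), (c2, b2))),
    )


def enumerate_tasks(fw: CriteriaFramework) -> list[ChoiceTask]:
    """All strict trade-off tasks, canonical orientation, deterministic order.

    For K criteria with m elicited levels each the count is
    C(K,2) * C(m,2)^2: one task per unordered pair of elicited-level steps
    on each unordered pair of criteria.  Dominated comparisons (one option
    at least as good on both criteria) are never emitted.
    """
    tasks = []
    names = sorted(c.name for c in fw.criteria)
    for c1, c2 in itertools.combinations(names, 2):
        e1 = sorted(fw.criterion(c1).elicited_ranks)
        e2 = sorted(fw.criterion(c2).elicited_ranks)
        pair_tasks = []
        for b1, a1 in itertools.combinations(e1, 2):  # a1 > b1
            for a2, b2 in itertools.combinations(e2, 2):  # a2 < b2
                pair_tasks.append(_make_task(c1, a1, b1, c2, a2, b2))
        pair_tasks.sort(
            key=lambda t: (
                -t.option_a.rank_on(c1),
                -t.option_a.rank_on(c2),
                -t.option_b.rank_on(c1),
                -t.option_b.rank_on(c2),
            )
        )
        tasks.extend(pair_tasks)
    return tasks


def dominance_edges(fw: CriteriaFramework, pair: frozenset[str]) -> dict:
    """Digraph over a pair's profile grid with an edge x -> y iff x strictly
    dominates y (at least as good on both criteria, better on one)."""
    c1, c2 = sorted(pair)
    e1 = sorted(fw.criterion(c1).elicited_ranks)
    e2 = sorted(fw.criterion(c2).elicited_ranks)
    nodes = [(r1, r2) for r1 in e1 for r2 in e2]
    g: dict[tuple[int, int], set] = {u: set() for u in nodes}
    for u in nodes:
        for v in nodes:
            if u != v and u[0] >= v[0] and u[1] >= v[1]:
                g[u].add(v)
    return g


def _reachable(g: dict, src, dst) -> bool:
    if src == dst:
        return True
    seen = {src}
    stack = [src]
    while stack:
        u = stack.pop()
        for v in g.get(u, ()):
            if v == dst:
                return True
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


def _ancestors(g: dict, node) -> set:
    rev: dict = {}
    for u, vs in g.items():
        for v in vs:
            rev.setdefault(v, set()).add(u)
    out = {node}
    stack = [node]
    while stack:
        u = stack.pop()
        for v in rev.get(u, ()):
            if v not in out:
                out.add(v)
                stack.append(v)
    return out


def _descendants(g: dict, node) -> set:
    out = {node}
    stack = [node]
    while stack:
        u = stack.pop()
        for v in g.get(u, ()):
            if v not in out:
                out.add(v)
                stack.append(v)
    return out


class PreferenceState:
    """The growing constraint system of one respondent's session.

    Tracks the partition of the enumerated task set into *answered*
    (explicitly asked), *implied* (ordering forced by the answers) and
    *undecided*, plus the LP constraint rows induced by the answers.
    """

    def __init__(self, fw: CriteriaFramework, margin: float = PROBE_MARGIN):
        self.fw = fw
        self.space = ConstraintSpace(fw, margin=margin)
        self.margin = float(margin)
        self.tasks = enumerate_tasks(fw)
        self.by_id = {t.task_id: t for t in self.tasks}
        self.answered: dict[str, str] = {}
        self.implied: dict[str, str] = {}
        self.undecided: set[str] = {t.task_id for t in self.tasks}
        self._graphs = {
            pair: dominance_edges(fw, pair)
            for pair in {t.pair for t in self.tasks}
        }
        self._tasks_by_pair: dict[frozenset, list[ChoiceTask]] = {}
        for t in self.tasks:
            self._tasks_by_pair.setdefault(t.pair, []).append(t)
        self._ub_rows: list[np.ndarray] = list(self.space.base_ub)
        self._ub_b: list[float] = list(self.space.base_ub_b)
        self._eq_rows: list[np.ndarray] = [self.space.norm_row]
        self._eq_b: list[float] = [TOTAL_POINTS]
        self._witnesses: list[np.ndarray] = []
        self._n_lp_solves = 0  # diagnostics

    # -- constraint bookkeeping -------------------------------------------

    def preferences(self) -> list[tuple[ChoiceTask, str]]:
        """Answered tasks as (task, answer) pairs, in answer order."""
        return [(self.by_id[tid], ans) for tid, ans in self.answered.items()]

    def _add_graph_edges(self, task: ChoiceTask, answer: str) -> None:
        g = self._graphs[task.pair]
        a, b = profile_key(task.option_a), profile_key(task.option_b)
        if answer == "A":
            g[a].add(b)
        elif answer == "B":
            g[b].add(a)
        else:  # EQUAL: at-least-as-good both ways
            g[a].add(b)
            g[b].add(a)

    def _add_lp_rows(self, task: ChoiceTask, answer: str) -> None:
        d = self.space.diff_vector(task)
        if answer == "A":
            self._ub_rows.append(-d)
            self._ub_b.append(-self.margin)
        elif answer == "B":
            self._ub_rows.append(d)
            self._ub_b.append(-self.margin)
        else:
            self._eq_rows.append(d)
            self._eq_b.append(0.0)
        # drop witnesses the new constraint invalidates
        if self._witnesses:
            if answer == "EQUAL":
                self._witnesses = [
                    w for w in self._witnesses if abs(float(d @ w)) <= FEAS_TOL
                ]
            else:
                row, b = self._ub_rows[-1], self._ub_b[-1]
                self._witnesses = [
                    w for w in self._witnesses if float(row @ w) <= b + FEAS_TOL
                ]

    def _solve_diff(self, d: np.ndarray, maximize: bool) -> float:
        """Optimise the value difference d.x over the current feasible set."""
        self._n_lp_solves += 1
        res = linprog(
            -d if maximize else d,
            A_ub=np.array(self._ub_rows),
            b_ub=np.array(self._ub_b),
            A_eq=np.array(self._eq_rows),
            b_eq=np.array(self._eq_b),
            bounds=(0.0, TOTAL_POINTS),
            method="highs",
        )
        if res.status != 0 or res.x is None:
            raise InconsistencyError(
                "elicitation state is infeasible - corrupted or contradictory input"
            )
        if len(self._witnesses) < 80:
            self._witnesses.append(res.x.copy())
        return float(d @ res.x)

    # -- implication ------------------------------------------------------

    def graph_ordering(self, task: ChoiceTask) -> str:
        """Ordering implied by dominance + recorded edges alone (sound,
        same-pair only).  Returns 'A', 'B', 'EQUAL' or 'UNDECIDED'."""
        g = self._graphs[task.pair]
        a, b = profile_key(task.option_a), profile_key(task.option_b)
        ab = _reachable(g, a, b)
        ba = _reachable(g, b, a)
        if ab and ba:
            return "EQUAL"
        if ab:
            return "A"
        if ba:
            return "B"
        return "UNDECIDED"

    def implied_ordering(self, task: ChoiceTask, lp_only: bool = False) -> str:
        """LP-backed implication: 'A' iff "B preferred" is infeasible given
        the recorded answers (and vice versa), 'EQUAL' iff both strict
        orderings are infeasible but equality is feasible, else 'UNDECIDED'.

        The graph shortcut settles same-pair chains without a solve; pass
        ``lp_only=True`` to force the LP route (used to cross-check that LP
        implication subsumes transitivity chaining).
        """
        if task.task_id not in self.by_id:
            raise KeyError(f"task {task.task_id} is not in the enumerated set")
        if not lp_only:
            verdict = self.graph_ordering(task)
            if verdict != "UNDECIDED":
                return verdict
        d = self.space.diff_vector(task)
        lo = hi = None
        a_feasible = b_feasible = False
        for w in self._witnesses:
            dv = float(d @ w)
            a_feasible = a_feasible or dv >= self.margin - FEAS_TOL
            b_feasible = b_feasible or dv <= -self.margin + FEAS_TOL
            if a_feasible and b_feasible:
                return "UNDECIDED"
        if not b_feasible:
            lo = self._solve_diff(d, maximize=False)
            b_feasible = lo <= -self.margin + FEAS_TOL
        if not a_feasible:
            hi = self._solve_diff(d, maximize=True)
            a_feasible = hi >= self.margin - FEAS_TOL
        if a_feasible and b_feasible:
            return "UNDECIDED"
        if a_feasible:
            return "A"
        if b_feasible:
            return "B"
        # both strict orderings infeasible: equality must be feasible
        if lo is None:
            lo = self._solve_diff(d, maximize=False)
        if hi is None:
            hi = self._solve_diff(d, maximize=True)
        if lo <= FEAS_TOL and hi >= -FEAS_TOL:
            return "EQUAL"
        return "UNDECIDED"  # pragma: no cover - degenerate numeric corner

    def record_answer(self, task: ChoiceTask, answer: str) -> "PreferenceState":
        """Record an explicit answer and propagate all newly forced orderings.

        Mutates and returns the state.  The task must currently be
        undecided; answers to resolved tasks raise
        :class:`AlreadyResolvedError`.
        """
        if answer not in ANSWERS:
            raise ValueError(f"answer must be one of {ANSWERS}, got {answer!r}")
        tid = task.task_id
        if tid not in self.undecided:
            raise AlreadyResolvedError(f"task {tid} is already resolved")
        self.undecided.remove(tid)
        self.answered[tid] = answer
        self._add_graph_edges(task, answer)
        self._add_lp_rows(task, answer)
        for other_id in [t.task_id for t in self.tasks if t.task_id in self.undecided]:
            verdict = self.implied_ordering(self.by_id[other_id])
            if verdict != "UNDECIDED":
                self.undecided.remove(other_id)
                self.implied[other_id] = verdict
                self._add_graph_edges(self.by_id[other_id], verdict)
        return self

    # -- question selection ----------------------------------------------

    def _graph_gain(self, task: ChoiceTask, answer: str) -> int:
        """How many other undecided same-pair tasks a hypothetical answer
        would settle by dominance/transitivity chaining."""
        g = self._graphs[task.pair]
        a, b = profile_key(task.option_a), profile_key(task.option_b)
        winner, loser = (a, b) if answer == "A" else (b, a)
        anc = _ancestors(g, winner)
        desc = _descendants(g, loser)
        gain = 0
        # undecided tasks are necessarily graph-open (graph implication is a
        # subset of LP implication), so membership in `undecided` suffices
        for t2 in self._tasks_by_pair[task.pair]:
            if t2.task_id == task.task_id or t2.task_id not in self.undecided:
                continue
            a2, b2 = profile_key(t2.option_a), profile_key(t2.option_b)
            if (a2 in anc and b2 in desc) or (b2 in anc and a2 in desc):
                gain += 1
        return gain


def implied_ordering(state: PreferenceState, task: ChoiceTask) -> str:
    return state.implied_ordering(task)


def record_answer(state: PreferenceState, task: ChoiceTask, answer: str) -> PreferenceState:
    return state.record_answer(task, answer)


def next_task(
    state: PreferenceState, strategy: str = "sequential", seed: int = 0
) -> ChoiceTask | None:
    """Select the next question, or None when every task is resolved.

    ``sequential`` asks the first undecided task in canonical order.
    ``greedy`` asks the undecided task with the best worst-case number of
    eliminations over its two strict answers (counted by same-pair
    dominance/transitivity chaining), ties broken by canonical order.
    Deterministic given the state and strategy; ``seed`` is accepted for
    interface symmetry with stochastic strategies.
    """
    open_tasks = [t for t in state.tasks if t.task_id in state.undecided]
    if not open_tasks:
        return None
    if strategy == "sequential":
        return open_tasks[0]
    if strategy == "greedy":
        best, best_score = open_tasks[0], -1
        for t in open_tasks:
            score = min(state._graph_gain(t, "A"), state._graph_gain(t, "B"))
            if score > best_score:
                best, best_score = t, score
        return best
    raise ValueError(f"unknown strategy {strategy!r}")


# -- sessions -------------------------------------------------------------


@dataclass
class Response:
    task_id: str
    answer: str
    rt_seconds: float
    is_repeat: bool = False
    sequence_index: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rt_seconds <= 0:
            raise ValueError("response time must be positive")
        if self.answer not in ANSWERS:
            raise ValueError(f"answer must be one of {ANSWERS}")


@dataclass
class Session:
    respondent_id: str
    group: str = "other"
    responses: list[Response] = field(default_factory=list)
    completed: bool = False
    consistency_correct: int = 0
    speeder: bool | None = None

    @property
    def answered_responses(self) -> list[Response]:
        return [r for r in self.responses if not r.is_repeat]

    @property
    def repeat_responses(self) -> list[Response]:
        return [r for r in self.responses if r.is_repeat]

    @property
    def n_answered(self) -> int:
        return len(self.answered_responses)

    def rts(self) -> list[float]:
        return [r.rt_seconds for r in self.responses]


def run_session(
    fw: CriteriaFramework,
    responder: Callable[[ChoiceTask], tuple[str, float]],
    strategy: str = "greedy",
    seed: int = 0,
    respondent_id: str = "r0",
    group: str = "other",
) -> Session:
    """Run one full adaptive session: question until every task is resolved,
    then re-ask two earlier tasks as a consistency check.

    The responder is called as ``responder(task) -> (answer, rt_seconds)``
    and may raise :class:`ResponderAborted`, in which case the partial
    session is returned with ``completed=False``.

    The repeats are the first and the (lower) median-index answered tasks,
    in that order; a repeat counts as consistent when it matches the
    original answer exactly.
    """
    state = PreferenceState(fw)
    session = Session(respondent_id=respondent_id, group=group)
    seq = 0
    try:
        while (task := next_task(state, strategy=strategy, seed=seed)) is not None:
            answer, rt = responder(task)
            state.record_answer(task, answer)
            seq += 1
            session.responses.append(
                Response(task.task_id, answer, rt, is_repeat=False, sequence_index=seq)
            )
        answered = session.answered_responses
        repeat_idx = [0, (len(answered) - 1) // 2]
        correct = 0
        for i in repeat_idx:
            original = answered[i]
            task = state.by_id[original.task_id]
            answer, rt = responder(task)
            seq += 1
            session.responses.append(
                Response(task.task_id, answer, rt, is_repeat=True, sequence_index=seq)
            )
            if answer == original.answer:
                correct += 1
        session.consistency_correct = correct
        session.completed = True
    except ResponderAborted:
        session.completed = False
    return session


def session_completed(fw: CriteriaFramework, session: Session) -> bool:
    """Whether the recorded answers resolve the full enumerated task set.

    Replays the non-repeat answers as one constraint block and checks that
    no enumerated task remains undecided.  Used when sessions come from a
    file rather than from :func:`run_session`.
    """
    state = PreferenceState(fw)
    for resp in session.answered_responses:
        task = state.by_id.get(resp.task_id)
        if task is None:
            raise KeyError(
                f"session {session.respondent_id}: unknown task id {resp.task_id!r}"
            )
        if resp.task_id in state.undecided:
            state.undecided.remove(resp.task_id)
        state.answered[resp.task_id] = resp.answer
        state._add_graph_edges(task, resp.answer)
        state._add_lp_rows(task, resp.answer)
    for t in state.tasks:
        if t.task_id in state.undecided:
            if state.implied_ordering(t) == "UNDECIDED":
                return False
    return True


# -- quality control ------------------------------------------------------


def _lower_median(xs: Sequence[float]) -> float:
    s = sorted(xs)
    return s[(len(s) - 1) // 2]


def flag_speeder(
    session: Session,
    min_rt: float = MIN_RT_SECONDS,
    min_median_rt: float = MIN_MEDIAN_RT_SECONDS,
) -> bool:
    """True when any response took under ``min_rt`` seconds or the median
    response time (over all responses, repeats included; lower median for
    even counts) is under ``min_median_rt`` seconds."""
    rts = session.rts()
    if not rts:
        raise ValueError("session has no responses")
    return min(rts) < min_rt or _lower_median(rts) < min_median_rt


@dataclass
class InclusionReport:
    included: list[Session]
    excluded_speeder: list[Session]
    non_completer: list[Session]
    consistency_tally: pd.DataFrame  # group x consistency_correct counts (included only)


def apply_inclusion_filters(
    sessions: Iterable[Session],
    min_rt: float = MIN_RT_SECONDS,
    min_median_rt: float = MIN_MEDIAN_RT_SECONDS,
) -> InclusionReport:
    """Partition sessions into included / speeder-excluded / non-completer.

    Only completed, non-speeder sessions are included.  Incomplete sessions
    go to ``non_completer`` regardless of speed.  The consistency tally
    counts included sessions by group and repeats answered consistently
    (0, 1 or 2).
    """
    included, speeders, noncomp = [], [], []
    for s in sessions:
        if not s.completed:
            noncomp.append(s)
            continue
        s.speeder = flag_speeder(s, min_rt=min_rt, min_median_rt=min_median_rt)
        if s.speeder:
            speeders.append(s)
        else:
            included.append(s)
    groups = sorted({s.group for s in included})
    tally = pd.DataFrame(0, index=groups, columns=[0, 1, 2], dtype=int)
    for s in included:
        tally.loc[s.group, min(s.consistency_correct, 2)] += 1
    tally.index.name = "group"
    tally.columns.name = "consistency_correct"
    return InclusionReport(included, speeders, noncomp, tally)
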