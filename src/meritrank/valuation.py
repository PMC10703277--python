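"""Point-value derivation from ordinal choice constraints.

Each respondent's pairwise answers are ordinal constraints on an additive
value function: one value per (criterion, elicited level), the lowest level
of every criterion anchored at 0 and the top-level values summing to 100 so
that proposal scores live on a 0-100 scale.  A two-stage linear program
turns the constraints into a concrete point system:

* stage 1 maximises the common separation margin ``eps`` by which every
  strict preference and every within-criterion level step is satisfied
  (``eps* > 0`` certifies the answers are consistent);
* stage 2 fixes ``eps = eps*`` and, among all maximum-margin systems,
  selects the one closest (in total absolute deviation) to a neutral
  reference grid with equal criterion importance and equally spaced levels,
  which makes the output deterministic.

Non-elicited levels are then filled by a monotone piecewise-cubic
(Fritsch-Carlson) interpolant, and per-respondent systems are aggregated
into group mean weights with SDs and t-based 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator
from scipy.optimize import linprog

from .framework import CriteriaFramework

if TYPE_CHECKING:  # pragma: no cover
    from .elicitation import ChoiceTask

__all__ = [
    "PointSystem",
    "ConstraintSpace",
    "InconsistencyError",
    "derive_point_values",
    "interpolate_levels",
    "aggregate_point_systems",
    "PROBE_MARGIN",
    "TOTAL_POINTS",
]

#: Separation margin (points on the 0-100 scale) used when testing whether a
#: strict ordering is feasible.  Well above solver tolerance, far below the
#: scale of any meaningful weight.
PROBE_MARGIN = 1e-3

#: Numerical slack when comparing LP objective values against the margin.
FEAS_TOL = 1e-6

#: The normalisation constant: top-level values sum to this.
TOTAL_POINTS = 100.0


class InconsistencyError(ValueError):
    """The recorded answers admit no additive value function."""


@dataclass
class PointSystem:
    """Per-criterion, per-level point values ("weights") on a 0-100 scale.

    ``values`` maps ``(criterion name, level rank)`` to points.  A derived
    system initially covers only the elicited levels; after interpolation it
    covers every level of the framework.
    """

    values: dict[tuple[str, int], float]
    provenance: str = ""

    def value(self, criterion: str, rank: int) -> float:
        try:
            return self.values[(criterion, rank)]
        except KeyError:
            raise KeyError(
                f"point system {self.provenance!r} has no value for "
                f"({criterion!r}, level {rank})"
            ) from None

    def top_sum(self, fw: CriteriaFramework) -> float:
        return float(sum(self.value(c.name, c.top_rank) for c in fw.criteria))

    def criterion_ranks(self, criterion: str) -> list[int]:
        return sorted(r for (c, r) in self.values if c == criterion)

    def validate(self, fw: CriteriaFramework, top_sum_tol: float = 1e-6) -> list[str]:
        """Invariant check; returns violation messages (empty = valid).

        ``top_sum_tol`` is widened (to +-0.5) for as-printed published
        systems whose rounded values need not sum exactly to 100.
        """
        problems: list[str] = []
        for c in fw.criteria:
            ranks = self.criterion_ranks(c.name)
            if not ranks:
                problems.append(f"no values for criterion {c.name!r}")
                continue
            if self.value(c.name, ranks[0]) != 0.0:
                problems.append(f"{c.name}: lowest level value is not 0")
            vals = [self.value(c.name, r) for r in ranks]
            if any(b < a - 1e-9 for a, b in zip(vals, vals[1:])):
                problems.append(f"{c.name}: values decrease with level rank")
        ts = self.top_sum(fw)
        if abs(ts - TOTAL_POINTS) > top_sum_tol:
            problems.append(f"top-level values sum to {ts}, not {TOTAL_POINTS}")
        return problems

    def to_frame(self, fw: CriteriaFramework) -> pd.DataFrame:
        rows = []
        for c in fw.criteria:
            for r in self.criterion_ranks(c.name):
                rows.append(
                    {
                        "criterion": c.name,
                        "level_rank": r,
                        "level_label": c.label_for(r),
                        "points": self.value(c.name, r),
                    }
                )
        return pd.DataFrame(rows)


class ConstraintSpace:
    """LP variable space over the elicited level values of a framework.

    One variable per (criterion, elicited level) excluding each criterion's
    lowest level, which is anchored at 0.  Provides the coefficient vectors
    for partial-profile comparisons and the base constraint system
    (monotone level steps, top-level normalisation) shared by the
    elicitation engine's feasibility probes and the weight derivation LP.
    """

    def __init__(self, fw: CriteriaFramework, margin: float = PROBE_MARGIN):
        self.fw = fw
        self.margin = float(margin)
        self.var_index: dict[tuple[str, int], int] = {}
        for c in fw.criteria:
            for r in c.elicited_ranks:
                if r != min(c.elicited_ranks):
                    self.var_index[(c.name, r)] = len(self.var_index)
        self.n_vars = len(self.var_index)

        # Monotone steps between consecutive elicited levels: step >= margin,
        # stored as -step <= -margin.
        ub_rows, ub_b = [], []
        for c in fw.criteria:
            ranks = sorted(c.elicited_ranks)
            for lo, hi in zip(ranks, ranks[1:]):
                row = np.zeros(self.n_vars)
                row[self.var_index[(c.name, hi)]] = -1.0
                if (c.name, lo) in self.var_index:
                    row[self.var_index[(c.name, lo)]] = 1.0
                ub_rows.append(row)
                ub_b.append(-self.margin)
        self.base_ub = np.array(ub_rows)
        self.base_ub_b = np.array(ub_b)

        norm = np.zeros(self.n_vars)
        for c in fw.criteria:
            norm[self.var_index[(c.name, c.top_rank)]] = 1.0
        self.norm_row = norm

    def cell_vector(self, criterion: str, rank: int) -> np.ndarray:
        v = np.zeros(self.n_vars)
        if (criterion, rank) in self.var_index:
            v[self.var_index[(criterion, rank)]] = 1.0
        return v

    def diff_vector(self, task: "ChoiceTask") -> np.ndarray:
        """Coefficients of value(option_a) - value(option_b)."""
        v = np.zeros(self.n_vars)
        for crit, rank in task.option_a.assignments:
            if (crit, rank) in self.var_index:
                v[self.var_index[(crit, rank)]] += 1.0
        for crit, rank in task.option_b.assignments:
            if (crit, rank) in self.var_index:
                v[self.var_index[(crit, rank)]] -= 1.0
        return v

    def reference_grid(self) -> np.ndarray:
        """Equal criterion importance, equal elicited-level spacing."""
        ref = np.zeros(self.n_vars)
        k = len(self.fw.criteria)
        for c in self.fw.criteria:
            ranks = sorted(c.elicited_ranks)
            m = len(ranks)
            for i, r in enumerate(ranks):
                if (c.name, r) in self.var_index:
                    ref[self.var_index[(c.name, r)]] = (i / (m - 1)) * TOTAL_POINTS / k
        return ref


def _preference_rows(
    space: ConstraintSpace, preferences: Iterable[tuple["ChoiceTask", str]]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Split answered tasks into strict rows (winner-loser diff) and equality rows."""
    strict, equal = [], []
    for task, answer in preferences:
        d = space.diff_vector(task)
        if answer == "A":
            strict.append(d)
        elif answer == "B":
            strict.append(-d)
        elif answer == "EQUAL":
            equal.append(d)
        else:
            raise ValueError(f"unknown answer {answer!r} for task {task.task_id}")
    return strict, equal


def derive_point_values(
    fw: CriteriaFramework,
    preferences: Iterable[tuple["ChoiceTask", str]],
    provenance: str = "",
) -> PointSystem:
    """Derive a respondent's point system from their answered choice tasks.

    ``preferences`` is an iterable of ``(task, answer)`` with answer in
    {"A", "B", "EQUAL"}.  Raises :class:`InconsistencyError` when the
    answers admit no strictly separating additive value function (this can
    only happen for externally supplied answer sets; the elicitation engine
    never asks a question whose answer would contradict earlier ones).
    """
    prefs = list(preferences)
    space = ConstraintSpace(fw)
    strict, equal = _preference_rows(space, prefs)
    n = space.n_vars

    # Stage 1: maximise the separation margin eps (variable n).
    ub_rows = [np.append(r, 1.0) for r in space.base_ub]  # -step + eps <= 0
    ub_b = [0.0] * len(ub_rows)
    for d in strict:
        ub_rows.append(np.append(-d, 1.0))  # eps - diff <= 0
        ub_b.append(0.0)
    eq_rows = [np.append(space.norm_row, 0.0)]
    eq_b = [TOTAL_POINTS]
    for d in equal:
        eq_rows.append(np.append(d, 0.0))
        eq_b.append(0.0)
    c1 = np.zeros(n + 1)
    c1[-1] = -1.0
    bounds = [(0.0, TOTAL_POINTS)] * n + [(0.0, None)]
    res1 = linprog(
        c1, A_ub=np.array(ub_rows), b_ub=np.array(ub_b),
        A_eq=np.array(eq_rows), b_eq=np.array(eq_b),
        bounds=bounds, method="highs",
    )
    if res1.status != 0 or res1.x is None or res1.x[-1] <= FEAS_TOL:
        eps = None if res1.x is None else float(res1.x[-1])
        cycle = _strict_cycle_message(fw, prefs)
        detail = cycle or (
            f"maximum separation margin is {eps}" if eps is not None else "infeasible constraint system"
        )
        raise InconsistencyError(f"answers admit no separating value function: {detail}")
    eps_star = float(res1.x[-1])

    # Stage 2: fix eps (minus a hair of solver slack) and pull toward the
    # neutral reference grid in L1, via auxiliary deviation variables t.
    eps_fix = eps_star * (1.0 - 1e-9) - 1e-12
    ref = space.reference_grid()
    ub2_rows, ub2_b = [], []
    for row, b in zip(space.base_ub, space.base_ub_b):
        ub2_rows.append(np.append(row, np.zeros(n)))
        ub2_b.append(-eps_fix)  # -step <= -eps
    for d in strict:
        ub2_rows.append(np.append(-d, np.zeros(n)))
        ub2_b.append(-eps_fix)
    for i in range(n):  # |v_i - ref_i| <= t_i
        for sign in (1.0, -1.0):
            row = np.zeros(2 * n)
            row[i] = sign
            row[n + i] = -1.0
            ub2_rows.append(row)
            ub2_b.append(sign * ref[i])
    eq2_rows = [np.append(space.norm_row, np.zeros(n))]
    eq2_b = [TOTAL_POINTS]
    for d in equal:
        eq2_rows.append(np.append(d, np.zeros(n)))
        eq2_b.append(0.0)
    c2 = np.concatenate([np.zeros(n), np.ones(n)])
    bounds2 = [(0.0, TOTAL_POINTS)] * n + [(0.0, None)] * n
    res2 = linprog(
        c2, A_ub=np.array(ub2_rows), b_ub=np.array(ub2_b),
        A_eq=np.array(eq2_rows), b_eq=np.array(eq2_b),
        bounds=bounds2, method="highs",
    )
    if res2.status != 0 or res2.x is None:  # pragma: no cover - stage 1 guarantees
        raise InconsistencyError("stage-2 regularisation LP failed unexpectedly")
    x = res2.x[:n]

    values: dict[tuple[str, int], float] = {}
    for c in fw.criteria:
        for r in sorted(c.elicited_ranks):
            if (c.name, r) in space.var_index:
                values[(c.name, r)] = float(x[space.var_index[(c.name, r)]])
            else:
                values[(c.name, r)] = 0.0
    return PointSystem(values=values, provenance=provenance)


def _strict_cycle_message(fw, prefs) -> str | None:
    """Look for a preference cycle among profiles on one criteria pair."""
    from .elicitation import dominance_edges, profile_key

    graphs: dict[frozenset, dict] = {}
    for task, answer in prefs:
        pair = frozenset(c for c, _ in task.option_a.assignments)
        g = graphs.setdefault(pair, dominance_edges(fw, pair))
        a, b = profile_key(task.option_a), profile_key(task.option_b)
        if answer == "A":
            g.setdefault(a, set()).add(b)
        elif answer == "B":
            g.setdefault(b, set()).add(a)
    for pair, g in graphs.items():
        cyc = _find_cycle(g)
        if cyc:
            names = " > ".join(str(node) for node in cyc)
            return f"preference cycle on criteria {sorted(pair)}: {names}"
    return None


def _find_cycle(g: dict) -> list | None:
    colour: dict = {}
    stack: list = []

    def dfs(u):
        colour[u] = 1
        stack.append(u)
        for v in g.get(u, ()):  # grey -> cycle
            if colour.get(v) == 1:
                return stack[stack.index(v):] + [v]
            if colour.get(v, 0) == 0:
                found = dfs(v)
                if found:
                    return found
        colour[u] = 2
        stack.pop()
        return None

    for u in list(g):
        if colour.get(u, 0) == 0:
            found = dfs(u)
            if found:
                return found
    return None


def interpolate_levels(ps: PointSystem, fw: CriteriaFramework) -> PointSystem:
    """Fill non-elicited levels by monotone piecewise-cubic interpolation.

    Uses the Fritsch-Carlson shape-preserving cubic Hermite interpolant
    through the (rank, value) pairs of the levels already present, so the
    result is monotone within each criterion and leaves the elicited values
    untouched.  Collinear elicited values therefore interpolate linearly,
    and a constant criterion stays constant.
    """
    values = dict(ps.values)
    for c in fw.criteria:
        have = ps.criterion_ranks(c.name)
        missing = [lv.rank for lv in c.levels if lv.rank not in have]
        if not missing:
            continue
        x = np.array(have, dtype=float)
        y = np.array([ps.value(c.name, r) for r in have])
        interp = PchipInterpolator(x, y)
        for r in missing:
            values[(c.name, r)] = float(interp(float(r)))
    return PointSystem(values=values, provenance=ps.provenance)


def aggregate_point_systems(
    systems: Sequence[PointSystem],
    fw: CriteriaFramework,
    groups: Sequence[str] | None = None,
    include_overall: bool = True,
) -> pd.DataFrame:
    """Mean weights with SD and t-based 95% CI, per group and overall.

    Systems must all cover the same cells (aggregate after interpolation so
    every level is represented, mirroring how group mean weights are
    reported).  A single respondent yields SD 0 and a degenerate CI at the
    mean, by convention.
    """
    if not systems:
        raise ValueError("no point systems to aggregate")
    cells = sorted(systems[0].values)
    for ps in systems[1:]:
        if sorted(ps.values) != cells:
            raise ValueError("point systems cover different (criterion, level) cells")
    if groups is None:
        groups = ["all"] * len(systems)
        include_overall = False
    if len(groups) != len(systems):
        raise ValueError("groups must parallel systems")

    by_group: dict[str, list[PointSystem]] = {}
    for g, ps in zip(groups, systems):
        by_group.setdefault(g, []).append(ps)
    if include_overall:
        by_group["all"] = list(systems)

    rows = []
    for g in by_group:
        members = by_group[g]
        n = len(members)
        for c in fw.criteria:
            for r in sorted({rk for (cn, rk) in cells if cn == c.name}):
                vals = np.array([ps.value(c.name, r) for ps in members])
                mean = float(vals.mean())
                sd = float(vals.std(ddof=1)) if n > 1 else 0.0
                if n > 1 and sd > 0:
                    half = float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
                else:
                    half = 0.0
                rows.append(
                    {
                        "group": g,
                        "criterion": c.name,
                        "level_rank": r,
                        "level_label": c.label_for(r),
                        "mean": mean,
                        "sd": sd,
                        "ci_low": mean - half,
                        "ci_high": mean + half,
                        "n": n,
                    }
                )
    return pd.DataFrame(rows)


def aggregate_to_point_system(agg: pd.DataFrame, group: str = "all") -> PointSystem:
    """Collapse an aggregate table back to a mean PointSystem for scoring."""
    sub = agg[agg["group"] == group]
    if sub.empty:
        raise KeyError(f"no group {group!r} in aggregate table")
    values = {
        (row["criterion"], int(row["level_rank"])): float(row["mean"])
        for _, row in sub.iterrows()
    }
    return PointSystem(values=values, provenance=f"mean:{group}")
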