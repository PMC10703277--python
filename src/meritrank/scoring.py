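"""Scoring, ranking and group comparison of research proposals.

A proposal is rated with one performance level per criterion; its total
score is the sum of the corresponding point values, which lies on a 0-100
scale because each criterion's lowest level is worth 0 and the top-level
values sum to 100.  Proposals are ranked by total score (competition
ranking: ties share the minimum rank) and can optionally be divided by
their cost for a merit-cost ratio.  Group comparisons use a one-way ANOVA
on each criterion's highest-level weight across stakeholder groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .framework import CriteriaFramework
from .valuation import PointSystem, aggregate_point_systems

__all__ = [
    "ProposalRating",
    "ScoredProposal",
    "AnovaResult",
    "score_proposal",
    "score_proposals",
    "rank_proposals",
    "merit_cost_ratio",
    "one_way_anova",
    "summarize_groups",
    "GroupSummary",
]


@dataclass
class ProposalRating:
    """A proposal's rated level (any rung of the ladder) per criterion."""

    proposal_id: str
    levels: dict[str, int]  # criterion name -> level rank
    cost: float | None = None


@dataclass
class ScoredProposal:
    proposal_id: str
    total_score: float
    rank: int | None = None
    merit_cost_ratio: float | None = None


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def score_proposal(ps: PointSystem, rating: ProposalRating) -> float:
    """Total score: the sum over criteria of the points at the rated level.

    The point system must cover every criterion of the rating (use an
    interpolated system so intermediate levels are scoreable); a missing
    criterion rating or an unknown level raises.
    """
    criteria = {c for c, _ in ps.values}
    missing = criteria - set(rating.levels)
    if missing:
        raise ValueError(
            f"proposal {rating.proposal_id!r} is missing ratings for {sorted(missing)}"
        )
    unknown = set(rating.levels) - criteria
    if unknown:
        raise ValueError(
            f"proposal {rating.proposal_id!r} rates unknown criteria {sorted(unknown)}"
        )
    return float(sum(ps.value(c, r) for c, r in rating.levels.items()))


def merit_cost_ratio(total_score: float, cost: float) -> float:
    """Points of merit per unit cost."""
    if cost is None or cost <= 0:
        raise ValueError("cost must be a positive amount")
    return float(total_score) / float(cost)


def rank_proposals(scored: Sequence[ScoredProposal]) -> list[ScoredProposal]:
    """Assign competition ranks ("1224"): descending score, ties share the
    minimum rank, stable by proposal_id within ties."""
    if not scored:
        raise ValueError("no proposals to rank")
    ordered = sorted(scored, key=lambda s: (-s.total_score, s.proposal_id))
    for i, s in enumerate(ordered):
        if i > 0 and s.total_score == ordered[i - 1].total_score:
            s.rank = ordered[i - 1].rank
        else:
            s.rank = i + 1
    return ordered


def score_proposals(
    ps: PointSystem, ratings: Sequence[ProposalRating]
) -> pd.DataFrame:
    """Score, rank and (where cost is given) merit-cost-rate proposals."""
    scored = []
    for rating in ratings:
        total = score_proposal(ps, rating)
        mcr = merit_cost_ratio(total, rating.cost) if rating.cost else None
        scored.append(ScoredProposal(rating.proposal_id, total, merit_cost_ratio=mcr))
    ranked = rank_proposals(scored)
    return pd.DataFrame(
        {
            "proposal_id": [s.proposal_id for s in ranked],
            "total_score": [s.total_score for s in ranked],
            "rank": [s.rank for s in ranked],
            "merit_cost_ratio": [s.merit_cost_ratio for s in ranked],
        }
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Fixed-effects one-way ANOVA from the between/within decomposition.

    Conventions for degenerate inputs: all values identical gives F = 0,
    p = 1; zero within-group variance with unequal means gives an infinite
    F and p = 0.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least one observation")
    n = sum(a.size for a in arrays)
    if n <= k:
        raise ValueError("need more observations than groups")
    grand = float(np.concatenate(arrays).mean())
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_between, df_within = k - 1, n - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, df_between, df_within, 1.0)
        return AnovaResult(float("inf"), df_between, df_within, 0.0)
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(F, df_between, df_within))
    return AnovaResult(float(F), df_between, df_within, p)


@dataclass
class GroupSummary:
    """Mean weights per group with a per-criterion top-level ANOVA."""

    weights: pd.DataFrame  # group x criterion x level mean/sd/ci table
    anova: pd.DataFrame  # one row per criterion: F, dfs, p on top-level weights


def summarize_groups(
    point_systems: Sequence[PointSystem],
    groups: Sequence[str],
    fw: CriteriaFramework,
) -> GroupSummary:
    """Group mean-weight table plus one ANOVA per criterion.

    The ANOVA compares the highest-level weight of each criterion across
    stakeholder groups (the level that carries a criterion's full
    importance).  Requires at least two groups.
    """
    if len(point_systems) != len(groups):
        raise ValueError("groups must parallel point systems")
    unique_groups = sorted(set(groups))
    if len(unique_groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    weights = aggregate_point_systems(
        point_systems, fw, groups=list(groups), include_overall=True
    )
    rows = []
    for c in fw.criteria:
        per_group = [
            [
                ps.value(c.name, c.top_rank)
                for ps, g in zip(point_systems, groups)
                if g == grp
            ]
            for grp in unique_groups
        ]
        res = one_way_anova(per_group)
        rows.append(
            {
                "criterion": c.name,
                "F": res.F,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "p": res.p,
            }
        )
    return GroupSummary(weights=weights, anova=pd.DataFrame(rows))
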