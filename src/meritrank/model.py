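"""Model/Results interface over the weight-estimation pipeline.

`PaprikaModel` bundles the estimation stages — inclusion filtering, LP
point-value derivation per respondent, monotone interpolation of the
non-elicited levels, and group aggregation — behind a statsmodels-like
surface: build the model from session data, call ``fit()``, and read the
estimates, uncertainties and comparisons off the results object.

    >>> model = PaprikaModel(sessions, framework)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.anova_by_group()
    >>> res.score(ratings)
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .elicitation import (
    MIN_MEDIAN_RT_SECONDS,
    MIN_RT_SECONDS,
    InclusionReport,
    Session,
    apply_inclusion_filters,
)
from .framework import CriteriaFramework
from .scoring import GroupSummary, ProposalRating, score_proposals, summarize_groups
from .valuation import (
    PointSystem,
    aggregate_point_systems,
    aggregate_to_point_system,
    derive_point_values,
    interpolate_levels,
)

__all__ = ["PaprikaModel", "PaprikaResults"]


class PaprikaModel:
    """Estimate stakeholder point systems from pairwise-ranking sessions.

    Parameters
    ----------
    sessions
        Completed (or partially completed) elicitation sessions.
    framework
        The criteria framework the sessions were elicited on.
    apply_qc
        Apply the inclusion filters (drop non-completers and speeders)
        before estimation.  Disable only for data that was pre-filtered.
    min_rt, min_median_rt
        Speeder thresholds in seconds.
    """

    def __init__(
        self,
        sessions: Sequence[Session],
        framework: CriteriaFramework,
        apply_qc: bool = True,
        min_rt: float = MIN_RT_SECONDS,
        min_median_rt: float = MIN_MEDIAN_RT_SECONDS,
    ):
        self.sessions = list(sessions)
        self.framework = framework
        self.apply_qc = apply_qc
        self.min_rt = min_rt
        self.min_median_rt = min_median_rt

    @classmethod
    def from_csv(
        cls, path: str | Path, framework: CriteriaFramework, **kwargs
    ) -> "PaprikaModel":
        from .io import read_sessions

        return cls(read_sessions(path, framework), framework, **kwargs)

    def fit(self, interpolate: bool = True) -> "PaprikaResults":
        """Derive one point system per included respondent and aggregate.

        Per respondent the answered (non-repeat) tasks define the ordinal
        constraint set; the two-stage LP turns it into a point system, and
        ``interpolate=True`` (the default) fills the non-elicited levels so
        the aggregate covers the full ladder.
        """
        from .elicitation import PreferenceState

        if self.apply_qc:
            report = apply_inclusion_filters(
                self.sessions, min_rt=self.min_rt, min_median_rt=self.min_median_rt
            )
            included = report.included
        else:
            report = None
            included = self.sessions
        if not included:
            raise ValueError("no sessions pass the inclusion filters")

        by_id = {t.task_id: t for t in PreferenceState(self.framework).tasks}
        systems, groups = [], []
        for s in included:
            prefs = [
                (by_id[r.task_id], r.answer) for r in s.answered_responses
            ]
            ps = derive_point_values(self.framework, prefs, provenance=s.respondent_id)
            if interpolate:
                ps = interpolate_levels(ps, self.framework)
            systems.append(ps)
            groups.append(s.group)
        weights = aggregate_point_systems(
            systems, self.framework, groups=groups, include_overall=True
        )
        return PaprikaResults(self, systems, groups, weights, report)


class PaprikaResults:
    """Fitted point systems, their aggregates and downstream analyses."""

    def __init__(
        self,
        model: PaprikaModel,
        point_systems: list[PointSystem],
        groups: list[str],
        weights: pd.DataFrame,
        inclusion: InclusionReport | None,
    ):
        self.model = model
        self.point_systems = point_systems
        self.groups = groups
        self.weights_ = weights
        self.inclusion_ = inclusion

    @property
    def n_respondents(self) -> int:
        return len(self.point_systems)

    def mean_point_system(self, group: str = "all") -> PointSystem:
        """The group-mean point system, used for committee-mode scoring."""
        return aggregate_to_point_system(self.weights_, group=group)

    def score(self, ratings: Sequence[ProposalRating], group: str = "all") -> pd.DataFrame:
        """Score, rank and merit-cost-rate proposals under the mean system."""
        return score_proposals(self.mean_point_system(group), ratings)

    def anova_by_group(self) -> GroupSummary:
        """Group mean-weight table plus per-criterion top-level ANOVA."""
        return summarize_groups(self.point_systems, self.groups, self.model.framework)

    def summary(self) -> str:
        fw = self.model.framework
        lines = [
            "Stakeholder mean point values (0-100 scale)",
            "=" * 58,
            f"respondents: {self.n_respondents}"
            + (
                f"  (excluded: {len(self.inclusion_.excluded_speeder)} speeders, "
                f"{len(self.inclusion_.non_completer)} non-completers)"
                if self.inclusion_ is not None
                else ""
            ),
        ]
        overall = self.weights_[self.weights_["group"] == "all"]
        if overall.empty:
            overall = self.weights_
        tab = overall[
            ["criterion", "level_label", "mean", "sd", "ci_low", "ci_high", "n"]
        ].copy()
        for col in ("mean", "sd", "ci_low", "ci_high"):
            tab[col] = tab[col].map(lambda v: f"{v:.1f}")
        lines.append(tab.to_string(index=False))
        lines.append("=" * 58)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PaprikaResults: {self.n_respondents} respondents>"
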