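"""Synthetic respondents and cohorts for end-to-end testing of the pipeline.

A simulated respondent carries a known additive point system (the "truth"),
answers each trade-off task by the sign of the true value difference —
optionally flipped with a small error probability, or declared EQUAL when
the difference falls below an indifference threshold — and takes a
lognormally distributed time per task.  A "speeder" persona answers with
response times capped below the 1-second QC threshold so that injected
speeders are flagged with certainty.

Cohorts emulate a multi-group stakeholder survey: per group, true
top-level weights are drawn from a Dirichlet distribution centred on the
group mean vector, interior elicited levels get fractions of the top value
drawn uniformly from a band, and configured fractions of speeders and
non-completers are injected.  The generator writes both the session data
and a truth sidecar so recovery can be checked exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .elicitation import ChoiceTask, ResponderAborted, Session, run_session
from .framework import CriteriaFramework
from .valuation import PointSystem, interpolate_levels

__all__ = [
    "RespondentModel",
    "GroupConfig",
    "CohortConfig",
    "sample_respondent",
    "simulate_answer",
    "make_responder",
    "generate_cohort",
    "answered_task_counts",
]

#: Hard cap (seconds) on a speeder persona's response times; keeps every
#: speeder response under the 1 s QC threshold by construction.
SPEEDER_RT_CAP = 0.9


@dataclass
class RespondentModel:
    """A synthetic survey participant with a known additive value system."""

    respondent_id: str
    group: str
    true_system: PointSystem  # full ladder, all levels
    error_rate: float = 0.0
    indiff_threshold: float = 0.0
    rt_median: float = 6.0
    rt_sigma: float = 0.5
    persona: str = "normal"  # "normal" | "speeder"
    seed: int = 0
    rng: np.random.Generator = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.indiff_threshold < 0:
            raise ValueError("indiff_threshold must be >= 0")
        if self.rng is None:
            self.rng = np.random.default_rng(self.seed)

    def profile_value(self, profile) -> float:
        return sum(self.true_system.value(c, r) for c, r in profile.assignments)


def sample_respondent(
    fw: CriteriaFramework,
    seed,
    respondent_id: str = "r0",
    group: str = "other",
    mean_top: np.ndarray | list[float] | None = None,
    concentration: float = 40.0,
    mid_band: tuple[float, float] = (0.4, 0.8),
    error_rate: float = 0.0,
    indiff_threshold: float = 0.0,
    rt_median: float = 6.0,
    rt_sigma: float = 0.5,
    persona: str = "normal",
) -> RespondentModel:
    """Draw one respondent with a random monotone additive value system.

    Top-level weights come from a Dirichlet centred on ``mean_top`` (equal
    shares by default) with the given ``concentration``; ``math.inf``
    concentration degenerates to the mean vector exactly.  Interior
    elicited levels get fractions of the top value drawn as sorted uniforms
    from ``mid_band``; the non-elicited levels are filled by the same
    monotone interpolant the pipeline itself uses.
    """
    rng = np.random.default_rng(seed)
    k = len(fw.criteria)
    if mean_top is None:
        p = np.full(k, 1.0 / k)
    else:
        p = np.asarray(mean_top, dtype=float)
        p = p / p.sum()
    if math.isinf(concentration):
        top = p * 100.0
    else:
        if concentration <= 0:
            raise ValueError("concentration must be positive (or inf)")
        top = rng.dirichlet(p * concentration) * 100.0

    values: dict[tuple[str, int], float] = {}
    for c, t in zip(fw.criteria, top):
        ranks = sorted(c.elicited_ranks)
        values[(c.name, ranks[0])] = 0.0
        values[(c.name, ranks[-1])] = float(t)
        interior = ranks[1:-1]
        if interior:
            fracs = np.sort(rng.uniform(mid_band[0], mid_band[1], size=len(interior)))
            for r, f in zip(interior, fracs):
                values[(c.name, r)] = float(f * t)
    ps = interpolate_levels(
        PointSystem(values=values, provenance=respondent_id), fw
    )
    if persona == "speeder":
        rt_median, rt_sigma = 0.5, 0.2
    return RespondentModel(
        respondent_id=respondent_id,
        group=group,
        true_system=ps,
        error_rate=error_rate,
        indiff_threshold=indiff_threshold,
        rt_median=rt_median,
        rt_sigma=rt_sigma,
        persona=persona,
        seed=0,
        rng=rng,
    )


def simulate_answer(
    model: RespondentModel, task: ChoiceTask, rng: np.random.Generator | None = None
) -> tuple[str, float]:
    """Answer one task under the respondent's true values.

    The answer is the sign of the true value difference; differences within
    the indifference threshold give EQUAL; strict answers are flipped with
    probability ``error_rate`` (errors never fabricate an EQUAL).  Response
    time is lognormal with the model's median and dispersion.
    """
    rng = rng if rng is not None else model.rng
    diff = model.profile_value(task.option_a) - model.profile_value(task.option_b)
    if abs(diff) <= model.indiff_threshold:
        answer = "EQUAL"
    else:
        answer = "A" if diff > 0 else "B"
        if model.error_rate > 0 and rng.random() < model.error_rate:
            answer = "B" if answer == "A" else "A"
    rt = float(rng.lognormal(mean=math.log(model.rt_median), sigma=model.rt_sigma))
    if model.persona == "speeder":
        rt = min(rt, SPEEDER_RT_CAP)
    return answer, max(rt, 1e-3)


def make_responder(model: RespondentModel, abort_after: int | None = None):
    """Wrap a respondent model as a ``responder(task) -> (answer, rt)``.

    ``abort_after`` simulates a non-completer who walks away after that
    many answers.
    """
    count = 0

    def responder(task: ChoiceTask) -> tuple[str, float]:
        nonlocal count
        if abort_after is not None and count >= abort_after:
            raise ResponderAborted(model.respondent_id)
        count += 1
        return simulate_answer(model, task)

    return responder


def answered_task_counts(
    fw: CriteriaFramework,
    n_respondents: int,
    seed: int,
    concentration: float = 4.0,
    mid_band: tuple[float, float] = (0.4, 0.8),
    strategy: str = "greedy",
) -> list[int]:
    """Explicitly answered (non-repeat) task counts for a simulated cohort.

    The question-burden study design: error-free respondents whose
    top-level weights are Dirichlet draws (``concentration=4`` with equal
    means is the flat Dirichlet(1,1,1,1)) scaled to 100 points, interior
    elicited levels at fractions drawn from ``mid_band``.  Burden is driven
    entirely by how much the adaptive engine can eliminate.
    """
    counts = []
    for i in range(n_respondents):
        child = np.random.SeedSequence([seed, i])
        model = sample_respondent(
            fw,
            seed=child,
            respondent_id=f"b{i:04d}",
            concentration=concentration,
            mid_band=mid_band,
            error_rate=0.0,
        )
        session = run_session(
            fw, make_responder(model), strategy=strategy, respondent_id=model.respondent_id
        )
        counts.append(session.n_answered)
    return counts


class GroupConfig(BaseModel):
    """One stakeholder group of a synthetic cohort."""

    name: str
    n: int = Field(ge=0)
    mean_top_weights: list[float] | None = None  # percentage points, sum 100
    concentration: float = 40.0
    error_rate: float = Field(default=0.05, ge=0.0, lt=0.5)
    indiff_threshold: float = 0.0
    speeder_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    noncompleter_fraction: float = Field(default=0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check_weights(self):
        if self.mean_top_weights is not None:
            s = sum(self.mean_top_weights)
            if abs(s - 100.0) > 1e-6:
                raise ValueError(f"mean_top_weights sum to {s}, expected 100")
        return self


class CohortConfig(BaseModel):
    groups: list[GroupConfig]
    mid_band: tuple[float, float] = (0.4, 0.8)
    rt_median: float = 6.0
    rt_sigma: float = 0.5
    strategy: str = "greedy"


def generate_cohort(
    fw: CriteriaFramework, config: CohortConfig, seed: int
) -> tuple[list[Session], dict[str, PointSystem]]:
    """Simulate a full multi-group cohort through the elicitation engine.

    Returns the sessions (speeders and non-completers included, for the QC
    stage to find) and a truth sidecar mapping respondent id to the true
    point system.  Fully deterministic given the master seed: per-respondent
    seeds are spawned from it.
    """
    sessions: list[Session] = []
    truth: dict[str, PointSystem] = {}
    for gi, gcfg in enumerate(config.groups):
        for i in range(gcfg.n):
            child = np.random.SeedSequence([seed, gi, i])
            rng = np.random.default_rng(child)
            rid = f"{gcfg.name}-{i:04d}"
            persona = "speeder" if rng.random() < gcfg.speeder_fraction else "normal"
            abort_after = None
            if rng.random() < gcfg.noncompleter_fraction:
                abort_after = int(rng.integers(1, 7))
            model = sample_respondent(
                fw,
                seed=child.spawn(1)[0],
                respondent_id=rid,
                group=gcfg.name,
                mean_top=gcfg.mean_top_weights,
                concentration=gcfg.concentration,
                mid_band=config.mid_band,
                error_rate=gcfg.error_rate,
                indiff_threshold=gcfg.indiff_threshold,
                rt_median=config.rt_median,
                rt_sigma=config.rt_sigma,
                persona=persona,
            )
            truth[rid] = model.true_system
            session = run_session(
                fw,
                make_responder(model, abort_after=abort_after),
                strategy=config.strategy,
                respondent_id=rid,
                group=gcfg.name,
            )
            sessions.append(session)
    return sessions, truth
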