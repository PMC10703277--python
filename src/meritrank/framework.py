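"""Criteria frameworks: the universe a preference-elicitation survey runs over.

A framework is an ordered list of criteria, each with an ordered ladder of
performance levels (worst first).  A subset of each criterion's levels is
marked *elicited*: only those levels appear in the pairwise choice tasks,
and the remaining levels are later filled in by monotone interpolation.
The default instance is the four-criterion research-merit framework
(Appropriateness, Significance, Relevance, Feasibility) with five levels
per criterion of which low / medium / high are elicited.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterator

import yaml
from pydantic import BaseModel, Field

__all__ = [
    "CriterionLevel",
    "Criterion",
    "CriteriaFramework",
    "FrameworkValidationError",
    "validate_framework",
    "load_framework",
    "save_framework",
    "default_framework",
]


class FrameworkValidationError(ValueError):
    """Raised when a framework violates its structural invariants."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid criteria framework:\n" + "\n".join(self.violations))


class CriterionLevel(BaseModel):
    """One rung of a criterion's performance ladder.

    ``rank`` is 1-based, worst-to-best; ``elicited`` marks levels that are
    shown in choice tasks (the end levels must always be elicited so the
    ladder is anchored).
    """

    label: str
    rank: int = Field(ge=1)
    elicited: bool = True


class Criterion(BaseModel):
    name: str
    clarification: str = ""
    levels: list[CriterionLevel]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def elicited_ranks(self) -> list[int]:
        return [lv.rank for lv in self.levels if lv.elicited]

    @property
    def top_rank(self) -> int:
        return max(lv.rank for lv in self.levels)

    def label_for(self, rank: int) -> str:
        for lv in self.levels:
            if lv.rank == rank:
                return lv.label
        raise KeyError(f"criterion {self.name!r} has no level rank {rank}")

    def rank_for(self, label: str) -> int:
        for lv in self.levels:
            if lv.label == label:
                return lv.rank
        raise KeyError(f"criterion {self.name!r} has no level labelled {label!r}")


class CriteriaFramework(BaseModel):
    name: str = "framework"
    version: str = "1"
    criteria: list[Criterion]

    def criterion(self, name: str) -> Criterion:
        for c in self.criteria:
            if c.name == name:
                return c
        raise KeyError(f"no criterion named {name!r}")

    @property
    def criterion_names(self) -> list[str]:
        return [c.name for c in self.criteria]

    def iter_cells(self) -> Iterator[tuple[str, int]]:
        """Yield every (criterion name, level rank) cell in framework order."""
        for c in self.criteria:
            for lv in c.levels:
                yield c.name, lv.rank


def validate_framework(fw: CriteriaFramework) -> list[str]:
    """Return a list of invariant-violation messages (empty list = valid)."""
    violations: list[str] = []
    if len(fw.criteria) < 2:
        violations.append("framework needs at least 2 criteria")
    seen: set[str] = set()
    for c in fw.criteria:
        if c.name in seen:
            violations.append(f"duplicate criterion name {c.name!r}")
        seen.add(c.name)
        if len(c.levels) < 2:
            violations.append(f"criterion {c.name!r} needs at least 2 levels")
            continue
        ranks = sorted(lv.rank for lv in c.levels)
        if ranks != list(range(1, len(c.levels) + 1)):
            violations.append(
                f"criterion {c.name!r}: level ranks {ranks} are not a permutation of 1..{len(c.levels)}"
            )
            continue
        labels = [lv.label for lv in c.levels]
        if len(set(labels)) != len(labels):
            violations.append(f"criterion {c.name!r} has duplicate level labels")
        elicited = c.elicited_ranks
        if len(elicited) < 2:
            violations.append(f"criterion {c.name!r} needs at least 2 elicited levels")
        if 1 not in elicited:
            violations.append(f"criterion {c.name!r}: lowest level must be elicited")
        if len(c.levels) not in elicited:
            violations.append(f"criterion {c.name!r}: highest level must be elicited")
    return violations


def _check(fw: CriteriaFramework) -> CriteriaFramework:
    violations = validate_framework(fw)
    if violations:
        raise FrameworkValidationError(violations)
    return fw


def default_elicited_ranks(n_levels: int) -> set[int]:
    """Default elicited subset: the two anchors plus the middle level."""
    return {1, math.ceil(n_levels / 2), n_levels}


def _framework_from_dict(doc: dict) -> CriteriaFramework:
    criteria = []
    for cdoc in doc.get("criteria", []):
        levels = []
        for i, ldoc in enumerate(cdoc.get("levels", []), start=1):
            if isinstance(ldoc, str):
                ldoc = {"label": ldoc}
            levels.append(
                CriterionLevel(
                    label=ldoc["label"],
                    rank=i,
                    elicited=bool(ldoc.get("elicited", True)),
                )
            )
        criteria.append(
            Criterion(
                name=cdoc["name"],
                clarification=cdoc.get("clarification", ""),
                levels=levels,
            )
        )
    return CriteriaFramework(
        name=doc.get("name", "framework"),
        version=str(doc.get("version", "1")),
        criteria=criteria,
    )


def load_framework(path: str | Path) -> CriteriaFramework:
    """Load and validate a framework from a YAML config file.

    Levels are listed worst-to-best; ranks are assigned from position.
    Raises :class:`FrameworkValidationError` when an invariant fails, and
    ``yaml.YAMLError`` / ``KeyError`` on malformed files.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise FrameworkValidationError(["config file does not contain a mapping"])
    return _check(_framework_from_dict(doc))


def save_framework(fw: CriteriaFramework, path: str | Path) -> None:
    doc = {
        "name": fw.name,
        "version": fw.version,
        "criteria": [
            {
                "name": c.name,
                "clarification": c.clarification,
                "levels": [
                    {"label": lv.label, "elicited": lv.elicited}
                    for lv in sorted(c.levels, key=lambda lv: lv.rank)
                ],
            }
            for c in fw.criteria
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def default_framework() -> CriteriaFramework:
    """The packaged four-criterion research-merit framework (ACTA)."""
    from .io import load_default_framework

    return load_default_framework()
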