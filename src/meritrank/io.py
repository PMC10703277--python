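"""File formats: sessions CSV, point-system JSON, proposals CSV, manifests.

The sessions CSV is the interchange format between elicitation, quality
control and weight derivation: one row per response with the fixed header

    respondent_id,group,sequence_index,task_id,crit_1,level_a1,level_b1,
    crit_2,level_a2,level_b2,answer,rt_seconds,is_repeat

(crit_1 is the lexicographically first criterion of the pair; option A's
and option B's level ranks on it are level_a1/level_b1, likewise for
crit_2).  Unknown extra columns round-trip untouched.

Also packaged here: the default four-criterion research-merit framework
and the published mean point system for it (stored exactly as printed —
its rounded top-level values sum to 100.1, so it is validated with an
as-printed tolerance rather than renormalised).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .elicitation import ANSWERS, Response, Session, enumerate_tasks, session_completed
from .framework import CriteriaFramework, load_framework
from .scoring import ProposalRating
from .valuation import PointSystem

__all__ = [
    "SESSIONS_HEADER",
    "SessionsSchemaError",
    "read_sessions",
    "write_sessions",
    "read_point_system",
    "write_point_system",
    "read_proposals",
    "load_default_framework",
    "load_reference_weights",
    "REFERENCE_TOP_SUM_TOL",
    "write_manifest",
]

SESSIONS_HEADER = [
    "respondent_id",
    "group",
    "sequence_index",
    "task_id",
    "crit_1",
    "level_a1",
    "level_b1",
    "crit_2",
    "level_a2",
    "level_b2",
    "answer",
    "rt_seconds",
    "is_repeat",
]

#: As-printed published weights are rounded to one decimal; their top-level
#: sum may miss 100 by up to this much without being renormalised.
REFERENCE_TOP_SUM_TOL = 0.5


class SessionsSchemaError(ValueError):
    """A sessions CSV violated the schema; the message names row and column."""


def load_default_framework() -> CriteriaFramework:
    with resources.as_file(
        resources.files("meritrank.data") / "default_framework.yaml"
    ) as p:
        return load_framework(p)


def load_reference_weights() -> PointSystem:
    """The packaged published mean point system for the default framework.

    Values are as printed (one decimal place); validate with
    ``top_sum_tol=REFERENCE_TOP_SUM_TOL``.
    """
    doc = json.loads(
        (resources.files("meritrank.data") / "acta_mean_weights.json").read_text()
    )
    values = {
        (row["criterion"], int(row["level_rank"])): float(row["points"])
        for row in doc["values"]
    }
    return PointSystem(values=values, provenance=doc.get("provenance", "published-mean"))


# -- sessions CSV ---------------------------------------------------------


def write_sessions(
    sessions: Iterable[Session], path: str | Path, fw: CriteriaFramework
) -> None:
    by_id = {t.task_id: t for t in enumerate_tasks(fw)}
    rows = []
    extra_cols: list[str] = []
    for s in sessions:
        for r in s.responses:
            task = by_id.get(r.task_id)
            if task is None:
                raise KeyError(f"task id {r.task_id!r} is not in the framework's task set")
            (c1, a1), (c2, a2) = task.option_a.assignments
            b1 = task.option_b.rank_on(c1)
            b2 = task.option_b.rank_on(c2)
            row = {
                "respondent_id": s.respondent_id,
                "group": s.group,
                "sequence_index": r.sequence_index,
                "task_id": r.task_id,
                "crit_1": c1,
                "level_a1": a1,
                "level_b1": b1,
                "crit_2": c2,
                "level_a2": a2,
                "level_b2": b2,
                "answer": r.answer,
                "rt_seconds": r.rt_seconds,
                "is_repeat": int(r.is_repeat),
            }
            for k, v in r.extras.items():
                row[k] = v
                if k not in extra_cols:
                    extra_cols.append(k)
            rows.append(row)
    df = pd.DataFrame(rows, columns=SESSIONS_HEADER + extra_cols)
    df.to_csv(path, index=False)


def read_sessions(
    path: str | Path, fw: CriteriaFramework, verify_completed: bool = True
) -> list[Session]:
    """Parse a sessions CSV back into Session objects.

    Schema violations raise :class:`SessionsSchemaError` naming the row.
    ``verify_completed`` replays each session's answers to decide whether
    the full task set was resolved (needed by the inclusion filters); pass
    False to skip the check when only raw responses are wanted.
    """
    df = pd.read_csv(path)
    missing = [c for c in SESSIONS_HEADER if c not in df.columns]
    if missing:
        raise SessionsSchemaError(f"missing columns: {missing}")
    extra_cols = [c for c in df.columns if c not in SESSIONS_HEADER]
    valid_ids = {t.task_id for t in enumerate_tasks(fw)}

    sessions: dict[str, Session] = {}
    for idx, row in df.iterrows():
        csv_row = idx + 2  # 1-based plus header
        rid = str(row["respondent_id"])
        if row["task_id"] not in valid_ids:
            raise SessionsSchemaError(
                f"row {csv_row}, column task_id: unknown task {row['task_id']!r}"
            )
        if row["answer"] not in ANSWERS:
            raise SessionsSchemaError(
                f"row {csv_row}, column answer: {row['answer']!r} not in {ANSWERS}"
            )
        try:
            rt = float(row["rt_seconds"])
        except (TypeError, ValueError):
            raise SessionsSchemaError(
                f"row {csv_row}, column rt_seconds: {row['rt_seconds']!r} is not a number"
            ) from None
        if not rt > 0:
            raise SessionsSchemaError(
                f"row {csv_row}, column rt_seconds: must be positive, got {rt}"
            )
        if int(row["is_repeat"]) not in (0, 1):
            raise SessionsSchemaError(
                f"row {csv_row}, column is_repeat: must be 0 or 1"
            )
        s = sessions.setdefault(rid, Session(respondent_id=rid, group=str(row["group"])))
        s.responses.append(
            Response(
                task_id=str(row["task_id"]),
                answer=str(row["answer"]),
                rt_seconds=rt,
                is_repeat=bool(int(row["is_repeat"])),
                sequence_index=int(row["sequence_index"]),
                extras={k: row[k] for k in extra_cols},
            )
        )

    out = []
    for s in sessions.values():
        s.responses.sort(key=lambda r: r.sequence_index)
        first_answer = {
            r.task_id: r.answer for r in reversed(s.answered_responses)
        }
        repeats = s.repeat_responses
        for r in repeats:
            if r.task_id not in first_answer:
                raise SessionsSchemaError(
                    f"session {s.respondent_id}: repeat of never-answered task {r.task_id!r}"
                )
        s.consistency_correct = sum(
            r.answer == first_answer[r.task_id] for r in repeats
        )
        s.completed = session_completed(fw, s) if verify_completed else False
        out.append(s)
    return out


# -- point-system JSON ----------------------------------------------------


def write_point_system(
    ps: PointSystem, path: str | Path, fw: CriteriaFramework
) -> None:
    doc = {
        "framework": fw.name,
        "provenance": ps.provenance,
        "values": [
            {
                "criterion": c.name,
                "level_rank": r,
                "level_label": c.label_for(r),
                "points": ps.value(c.name, r),
            }
            for c in fw.criteria
            for r in ps.criterion_ranks(c.name)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_point_system(path: str | Path) -> PointSystem:
    doc = json.loads(Path(path).read_text())
    values = {
        (row["criterion"], int(row["level_rank"])): float(row["points"])
        for row in doc["values"]
    }
    return PointSystem(values=values, provenance=doc.get("provenance", ""))


# -- proposals CSV --------------------------------------------------------


def read_proposals(path: str | Path, fw: CriteriaFramework) -> list[ProposalRating]:
    """Proposals CSV: proposal_id, one level-label column per criterion,
    optional cost column."""
    df = pd.read_csv(path)
    if "proposal_id" not in df.columns:
        raise SessionsSchemaError("proposals CSV needs a proposal_id column")
    missing = [c.name for c in fw.criteria if c.name not in df.columns]
    if missing:
        raise SessionsSchemaError(f"proposals CSV missing criterion columns: {missing}")
    ratings = []
    for idx, row in df.iterrows():
        levels = {}
        for c in fw.criteria:
            label = str(row[c.name])
            try:
                levels[c.name] = c.rank_for(label)
            except KeyError:
                raise SessionsSchemaError(
                    f"row {idx + 2}, column {c.name}: unknown level {label!r}"
                ) from None
        cost = None
        if "cost" in df.columns and pd.notna(row["cost"]):
            cost = float(row["cost"])
        ratings.append(ProposalRating(str(row["proposal_id"]), levels, cost))
    return ratings


# -- run manifests --------------------------------------------------------


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_path: str | Path,
    command: str,
    seed: int | None = None,
    inputs: Sequence[str | Path] = (),
    outputs: Sequence[str | Path] = (),
    config: dict | None = None,
) -> Path:
    """Write a JSON manifest recording what a CLI run read and produced."""
    from . import __version__

    manifest = {
        "command": command,
        "seed": seed,
        "version": __version__,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "config": config or {},
        "inputs": {str(p): _digest(p) for p in inputs if Path(p).exists()},
        "outputs": {str(p): _digest(p) for p in outputs if Path(p).exists()},
    }
    path = Path(out_path)
    path.write_text(json.dumps(manifest, indent=1))
    return path
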