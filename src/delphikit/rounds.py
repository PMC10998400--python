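"""Round workflow: decision ledgers transforming questionnaire versions.

A RAND-modified Delphi study proceeds in stages: drafting, a rating
(questionnaire) round, a consensus meeting, a final evaluation and the
final questionnaire. The panel's decisions at each stage — keep, drop,
promote (rescue an item the automatic triage had left orange or red),
add, or modify wording — are recorded in an explicit, auditable
:class:`DecisionLedger` rather than inferred from the triage, because
the meeting routinely overrides the automatic classification.

Applying a ledger to a questionnaire version yields the next version
plus a :class:`ChangeSummary`; :func:`audit_trail` replays a whole chain
and checks the conservation identity ``items_out = kept + promoted +
added`` at every stage. Items without an explicit decision are kept, so
an empty ledger is the identity transform. ``MODIFY`` rewords an item
(or question) and counts as kept. Questions left with no item are
removed, as are parts left with no question.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml
from pydantic import BaseModel, ValidationError, model_validator

from .errors import LedgerError, ParseError, SchemaError
from .panel_data import Item, Part, Question, QuestionnaireVersion
from .selection import ItemVerdict, Status

__all__ = [
    "Stage",
    "Action",
    "Decision",
    "DecisionLedger",
    "ChangeSummary",
    "apply_ledger",
    "audit_trail",
    "read_ledger",
    "write_ledger",
    "write_changes",
]


class Stage(str, Enum):
    QUESTIONNAIRE_ROUND = "questionnaire_round"
    CONSENSUS_ROUND = "consensus_round"
    FINAL_EVALUATION = "final_evaluation"


class Action(str, Enum):
    KEEP = "keep"
    DROP = "drop"
    PROMOTE = "promote"
    ADD = "add"
    MODIFY = "modify"


class Decision(BaseModel):
    """One panel decision about one item or question.

    ``target`` names an existing item or question id, except for ``ADD``
    where the payload carries the new content: either a whole ``question``
    (with ``part_id``) or a single ``item`` (with ``question_id``).
    ``MODIFY`` requires ``new_text`` and changes wording only.
    """

    target: Optional[str] = None
    action: Action
    rationale: str = ""
    # ADD payloads
    question: Optional[Question] = None
    part_id: Optional[str] = None
    item: Optional[Item] = None
    question_id: Optional[str] = None
    # MODIFY payload
    new_text: Optional[str] = None

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _payload_matches_action(self) -> "Decision":
        if self.action is Action.ADD:
            as_question = self.question is not None and self.part_id is not None
            as_item = self.item is not None and self.question_id is not None
            if as_question == as_item:
                raise ValueError(
                    "ADD needs exactly one payload: (question, part_id) or "
                    "(item, question_id)"
                )
            added_id = (
                self.question.question_id if as_question else self.item.item_id
            )
            if self.target is not None and self.target != added_id:
                raise ValueError("ADD target must match the payload id")
            object.__setattr__(self, "__dict__", {**self.__dict__, "target": added_id})
        else:
            if self.target is None:
                raise ValueError(f"{self.action.value} requires a target id")
            if self.action is Action.MODIFY and self.new_text is None:
                raise ValueError("MODIFY requires new_text")
        return self


class DecisionLedger(BaseModel):
    stage: Stage
    decisions: tuple[Decision, ...] = ()

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _one_decision_per_target(self) -> "DecisionLedger":
        targets = [d.target for d in self.decisions]
        if len(set(targets)) != len(targets):
            dupes = sorted({t for t in targets if targets.count(t) > 1})
            raise ValueError(f"multiple decisions for target(s): {', '.join(dupes)}")
        return self


@dataclass(frozen=True)
class ChangeSummary:
    """Item-level bookkeeping of one ledger application."""

    stage: Stage
    items_in: int
    kept: int
    dropped: int
    promoted: int
    added: int
    modified: int
    items_out: int
    questions_out: int

    def conserved(self) -> bool:
        return (
            self.items_out == self.kept + self.promoted + self.added
            and self.dropped == self.items_in - self.kept - self.promoted
        )


def _resolve_targets(
    version: QuestionnaireVersion, ledger: DecisionLedger
) -> dict[str, Decision]:
    """Expand question-level decisions to their items; validate ids."""
    item_ids = set(version.item_ids())
    question_items = {
        q.question_id: [it.item_id for it in q.items]
        for _, q in version.iter_questions()
    }
    per_item: dict[str, Decision] = {}

    def assign(item_id: str, decision: Decision) -> None:
        if item_id in per_item:
            raise LedgerError(
                f"item {item_id!r} is targeted by more than one decision"
            )
        per_item[item_id] = decision

    for d in ledger.decisions:
        if d.action is Action.ADD:
            if d.question is not None:
                if d.question.question_id in question_items:
                    raise LedgerError(
                        f"ADD of existing question {d.question.question_id!r}"
                    )
            else:
                if d.item.item_id in item_ids:
                    raise LedgerError(f"ADD of existing item {d.item.item_id!r}")
                if d.question_id not in question_items:
                    raise LedgerError(
                        f"ADD item into unknown question {d.question_id!r}"
                    )
            continue
        if d.target in item_ids:
            assign(d.target, d)
        elif d.target in question_items:
            for item_id in question_items[d.target]:
                assign(item_id, d)
        else:
            raise LedgerError(
                f"decision targets unknown id {d.target!r} "
                f"(stage {ledger.stage.value})"
            )
    return per_item


def apply_ledger(
    version: QuestionnaireVersion,
    verdicts: Optional[Mapping[str, ItemVerdict]],
    ledger: DecisionLedger,
    new_label: Optional[str] = None,
) -> tuple[QuestionnaireVersion, ChangeSummary]:
    """Apply a stage's decisions, producing the next questionnaire version.

    ``verdicts`` (from the triage of the incoming round) are required to
    validate ``PROMOTE`` decisions: only items previously up for
    discussion or not selected can be promoted. Items without an explicit
    decision are kept.
    """
    per_item = _resolve_targets(version, ledger)

    for item_id, d in per_item.items():
        if d.action is Action.PROMOTE:
            if verdicts is None or item_id not in verdicts:
                raise LedgerError(
                    f"PROMOTE of {item_id!r} requires a verdict for the item"
                )
            if verdicts[item_id].status is Status.SELECTED:
                raise LedgerError(
                    f"PROMOTE of {item_id!r}, which is already selected"
                )

    kept = dropped = promoted = added = modified = 0
    new_parts: list[Part] = []
    for part in version.parts:
        new_questions: list[Question] = []
        for q in part.questions:
            q_decision = per_item.get(q.items[0].item_id)
            new_items: list[Item] = []
            for it in q.items:
                d = per_item.get(it.item_id)
                action = d.action if d is not None else Action.KEEP
                if action is Action.DROP:
                    dropped += 1
                    continue
                if action is Action.PROMOTE:
                    promoted += 1
                    new_items.append(it)
                    continue
                kept += 1
                if action is Action.MODIFY:
                    modified += 1
                    # question-level MODIFY rewords the question, not items
                    if d.target == it.item_id:
                        it = it.model_copy(update={"text": d.new_text})
                new_items.append(it)
            if not new_items:
                continue  # question lost all its items
            text = q.text
            if (
                q_decision is not None
                and q_decision.action is Action.MODIFY
                and q_decision.target == q.question_id
            ):
                text = q_decision.new_text
            new_questions.append(
                Question(
                    question_id=q.question_id,
                    text=text,
                    response_format=q.response_format,
                    items=tuple(new_items),
                )
            )
        # ADD whole questions at the end of their part
        for d in ledger.decisions:
            if (
                d.action is Action.ADD
                and d.question is not None
                and d.part_id == part.part_id
            ):
                new_questions.append(d.question)
                added += len(d.question.items)
        if new_questions:
            new_parts.append(
                Part(
                    part_id=part.part_id,
                    title=part.title,
                    ranking_depth=part.ranking_depth,
                    questions=tuple(new_questions),
                )
            )
    # ADD single items into surviving questions
    item_adds = [
        d for d in ledger.decisions if d.action is Action.ADD and d.item is not None
    ]
    if item_adds:
        adds_by_question: dict[str, list[Item]] = {}
        for d in item_adds:
            adds_by_question.setdefault(d.question_id, []).append(d.item)
            added += 1
        patched_parts = []
        for part in new_parts:
            questions = []
            for q in part.questions:
                extra = adds_by_question.pop(q.question_id, [])
                if extra:
                    q = Question(
                        question_id=q.question_id,
                        text=q.text,
                        response_format=q.response_format,
                        items=tuple(q.items) + tuple(extra),
                    )
                questions.append(q)
            patched_parts.append(
                Part(
                    part_id=part.part_id,
                    title=part.title,
                    ranking_depth=part.ranking_depth,
                    questions=tuple(questions),
                )
            )
        if adds_by_question:
            raise LedgerError(
                "ADD item into question(s) absent from the produced version: "
                + ", ".join(sorted(adds_by_question))
            )
        new_parts = patched_parts

    if not new_parts:
        raise LedgerError("ledger would remove every part of the questionnaire")

    label = new_label or f"{version.version_label}+{ledger.stage.value}"
    new_version = QuestionnaireVersion(
        version_label=label, provenance=ledger.stage.value, parts=tuple(new_parts)
    )
    summary = ChangeSummary(
        stage=ledger.stage,
        items_in=version.n_items,
        kept=kept,
        dropped=dropped,
        promoted=promoted,
        added=added,
        modified=modified,
        items_out=new_version.n_items,
        questions_out=new_version.n_questions,
    )
    assert summary.conserved(), "conservation identity violated"
    return new_version, summary


def audit_trail(
    versions: Sequence[QuestionnaireVersion],
    ledgers: Sequence[DecisionLedger],
    verdicts_per_stage: Optional[Sequence[Optional[Mapping[str, ItemVerdict]]]] = None,
) -> list[dict]:
    """Replay a chain of versions and ledgers; verify consistency.

    ``versions`` has one more element than ``ledgers``; stage ``i`` must
    transform ``versions[i]`` into ``versions[i+1]`` (compared by item and
    question id sets). Returns one report row per stage with the counts
    and the conservation check.
    """
    if len(versions) != len(ledgers) + 1:
        raise LedgerError(
            f"chain mismatch: {len(versions)} versions vs {len(ledgers)} ledgers"
        )
    if verdicts_per_stage is None:
        verdicts_per_stage = [None] * len(ledgers)
    if len(verdicts_per_stage) != len(ledgers):
        raise LedgerError("one verdicts mapping (or None) per ledger is required")

    rows: list[dict] = []
    for i, ledger in enumerate(ledgers):
        produced, summary = apply_ledger(versions[i], verdicts_per_stage[i], ledger)
        expected = versions[i + 1]
        if set(produced.item_ids()) != set(expected.item_ids()) or set(
            produced.question_ids()
        ) != set(expected.question_ids()):
            raise LedgerError(
                f"stage {ledger.stage.value}: ledger output does not match the "
                f"recorded next version"
            )
        rows.append(
            {
                "stage": ledger.stage.value,
                "items_in": summary.items_in,
                "questions_in": versions[i].n_questions,
                "kept": summary.kept,
                "dropped": summary.dropped,
                "promoted": summary.promoted,
                "added": summary.added,
                "modified": summary.modified,
                "items_out": summary.items_out,
                "questions_out": summary.questions_out,
                "conserved": summary.conserved(),
            }
        )
    return rows


# ---------------------------------------------------------------------------
# YAML / CSV I/O
# ---------------------------------------------------------------------------


def read_ledger(path) -> DecisionLedger:
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        obj = yaml.safe_load(fh)
    if not isinstance(obj, dict):
        raise ParseError("ledger file does not hold a mapping", path=path)
    try:
        return DecisionLedger.model_validate(obj)
    except ValidationError as exc:
        raise SchemaError(f"invalid ledger in {path}: {exc}") from None


def write_ledger(ledger: DecisionLedger, path) -> None:
    obj = ledger.model_dump(mode="json", exclude_none=True)
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False, allow_unicode=True)


def write_changes(ledger: DecisionLedger, summary: ChangeSummary, path) -> None:
    """Write the per-decision change log plus a summary row."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["target", "action", "rationale"])
        for d in ledger.decisions:
            writer.writerow([d.target, d.action.value, d.rationale])
        writer.writerow([])
        writer.writerow(
            ["# summary", f"stage={summary.stage.value}", ""]
        )
        writer.writerow(
            [
                f"items_in={summary.items_in}",
                f"kept={summary.kept};dropped={summary.dropped};"
                f"promoted={summary.promoted};added={summary.added}",
                f"items_out={summary.items_out};questions_out={summary.questions_out}",
            ]
        )
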