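"""Bundled fixtures: the development chain of the A&F evaluation study.

Four shipped artifacts let the round arithmetic of the study be replayed
end to end:

* ``synthetic_round1_questionnaire.yaml`` — a SYNTHETIC stand-in for the
  initial 34-question / 57-item questionnaire. The real item texts were
  never published; the structure (sub-item numbering, part layout) and
  the ids referenced by the published decisions are faithful, the
  wording is invented.
* ``synthetic_round1_verdicts.csv`` — SYNTHETIC per-item triage statuses
  constrained to the published totals (34 selected / 16 up for
  discussion / 7 not selected) and to the published fate of the items
  named in the results (promoted, rescued or dropped ids).
* ``consensus_ledger.yaml`` / ``final_evaluation_ledger.yaml`` — the
  panel's published decisions: 31 of the 34 selected items kept, 10
  discussion items and 2 not-selected items promoted after rewording,
  one new question added (44 items over 31 questions), then one question
  dropped at final evaluation (43 items over 30 questions).
* ``final_questionnaire.yaml`` — the published final instrument:
  30 questions / 43 items in five sections.
"""

from __future__ import annotations

import csv
from importlib import resources

from .panel_data import QuestionnaireVersion, read_questionnaire
from .rounds import ChangeSummary, DecisionLedger, apply_ledger, read_ledger
from .selection import Consensus, ItemVerdict, Preselection, Status

__all__ = [
    "load_initial_questionnaire",
    "load_initial_verdicts",
    "load_consensus_ledger",
    "load_final_evaluation_ledger",
    "load_final_questionnaire",
    "development_chain",
]

_DATA = resources.files(__package__) / "data"

# canonical rule outcomes consistent with each stored triage status
_STATUS_TO_OUTCOMES = {
    Status.SELECTED: (Preselection.SELECTION, Consensus.CONSENSUS),
    Status.UP_FOR_DISCUSSION: (Preselection.SELECTION, Consensus.DISCUSSION),
    Status.NOT_SELECTED: (Preselection.NO_SELECTION, Consensus.NO_CONSENSUS),
}


def _data_path(name: str):
    return resources.as_file(_DATA / name)


def load_initial_questionnaire() -> QuestionnaireVersion:
    with _data_path("synthetic_round1_questionnaire.yaml") as p:
        return read_questionnaire(p)


def load_initial_verdicts() -> dict[str, ItemVerdict]:
    """Per-item triage statuses of the rating round (synthetic key)."""
    verdicts: dict[str, ItemVerdict] = {}
    with _data_path("synthetic_round1_verdicts.csv") as p, open(
        p, newline="", encoding="utf-8"
    ) as fh:
        for row in csv.DictReader(fh):
            status = Status(row["status"])
            pre, cons = _STATUS_TO_OUTCOMES[status]
            verdicts[row["item_id"]] = ItemVerdict(row["item_id"], pre, cons, status)
    return verdicts


def load_consensus_ledger() -> DecisionLedger:
    with _data_path("consensus_ledger.yaml") as p:
        return read_ledger(p)


def load_final_evaluation_ledger() -> DecisionLedger:
    with _data_path("final_evaluation_ledger.yaml") as p:
        return read_ledger(p)


def load_final_questionnaire() -> QuestionnaireVersion:
    with _data_path("final_questionnaire.yaml") as p:
        return read_questionnaire(p)


def development_chain() -> tuple[
    list[QuestionnaireVersion], list[DecisionLedger], list[ChangeSummary]
]:
    """Replay the full development chain from the shipped fixtures.

    Returns the three questionnaire versions (57 → 44 → 43 items), the
    two ledgers applied, and the per-stage change summaries.
    """
    v0 = load_initial_questionnaire()
    verdicts = load_initial_verdicts()
    consensus_ledger = load_consensus_ledger()
    final_ledger = load_final_evaluation_ledger()
    v1, s1 = apply_ledger(v0, verdicts, consensus_ledger)
    v2, s2 = apply_ledger(v1, None, final_ledger)
    return [v0, v1, v2], [consensus_ledger, final_ledger], [s1, s2]
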