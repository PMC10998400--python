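"""Decision ledgers: the published development chain and ledger algebra."""

from __future__ import annotations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from delphikit.datasets import (
    development_chain,
    load_consensus_ledger,
    load_final_evaluation_ledger,
    load_final_questionnaire,
    load_initial_questionnaire,
    load_initial_verdicts,
)
from delphikit.errors import LedgerError
from delphikit.panel_data import Item, Question
from delphikit.rounds import (
    Action,
    Decision,
    DecisionLedger,
    Stage,
    apply_ledger,
    audit_trail,
    read_ledger,
    write_ledger,
)
from delphikit.selection import Consensus, ItemVerdict, Preselection, Status


def _verdict(item_id, status):
    pre, cons = {
        Status.SELECTED: (Preselection.SELECTION, Consensus.CONSENSUS),
        Status.UP_FOR_DISCUSSION: (Preselection.SELECTION, Consensus.DISCUSSION),
        Status.NOT_SELECTED: (Preselection.NO_SELECTION, Consensus.NO_CONSENSUS),
    }[status]
    return ItemVerdict(item_id, pre, cons, status)


class TestPublishedChain:
    def test_round1_fixture_dimensions(self):
        v0 = load_initial_questionnaire()
        assert v0.n_items == 57 and v0.n_questions == 34

    def test_round1_verdict_counts(self):
        verdicts = load_initial_verdicts()
        counts = {s: 0 for s in Status}
        for v in verdicts.values():
            counts[v.status] += 1
        assert counts[Status.SELECTED] == 34
        assert counts[Status.UP_FOR_DISCUSSION] == 16
        assert counts[Status.NOT_SELECTED] == 7

    def test_consensus_round_yields_44_items_over_31_questions(self):
        v0 = load_initial_questionnaire()
        v1, summary = apply_ledger(
            v0, load_initial_verdicts(), load_consensus_ledger()
        )
        assert summary.kept == 31
        assert summary.promoted == 12
        assert summary.added == 1
        assert v1.n_items == 44 and v1.n_questions == 31

    def test_final_evaluation_drops_one_question(self):
        versions, _, _ = development_chain()
        assert versions[1].n_questions == 31
        assert versions[2].n_questions == 30 and versions[2].n_items == 43
        assert "11" not in versions[2].question_ids()

    def test_audit_trail_reports_the_whole_chain(self):
        versions, ledgers, _ = development_chain()
        rows = audit_trail(
            versions, ledgers, [load_initial_verdicts(), None]
        )
        assert [r["items_in"] for r in rows] == [57, 44]
        assert [r["items_out"] for r in rows] == [44, 43]
        assert [r["questions_out"] for r in rows] == [31, 30]
        assert all(r["conserved"] for r in rows)

    def test_final_fixture_matches_the_published_instrument(self):
        final = load_final_questionnaire()
        assert final.n_questions == 30 and final.n_items == 43
        assert [p.part_id for p in final.parts] == [
            "part1",
            "part2_1",
            "part2_2",
            "part2_3",
            "part2_4",
        ]


class TestApplyLedger:
    def test_empty_ledger_is_identity(self, tiny_questionnaire):
        ledger = DecisionLedger(stage=Stage.CONSENSUS_ROUND, decisions=())
        out, summary = apply_ledger(tiny_questionnaire, None, ledger)
        assert out.item_ids() == tiny_questionnaire.item_ids()
        assert summary.kept == tiny_questionnaire.n_items
        assert summary.dropped == summary.promoted == summary.added == 0

    def test_unknown_target_rejected(self, tiny_questionnaire):
        ledger = DecisionLedger(
            stage=Stage.CONSENSUS_ROUND,
            decisions=(Decision(target="ghost", action=Action.DROP),),
        )
        with pytest.raises(LedgerError, match="unknown id"):
            apply_ledger(tiny_questionnaire, None, ledger)

    def test_promote_of_selected_item_rejected(self, tiny_questionnaire):
        verdicts = {"q1": _verdict("q1", Status.SELECTED)}
        ledger = DecisionLedger(
            stage=Stage.CONSENSUS_ROUND,
            decisions=(Decision(target="q1", action=Action.PROMOTE),),
        )
        with pytest.raises(LedgerError, match="already selected"):
            apply_ledger(tiny_questionnaire, verdicts, ledger)

    def test_promote_without_verdicts_rejected(self, tiny_questionnaire):
        ledger = DecisionLedger(
            stage=Stage.CONSENSUS_ROUND,
            decisions=(Decision(target="q1", action=Action.PROMOTE),),
        )
        with pytest.raises(LedgerError, match="verdict"):
            apply_ledger(tiny_questionnaire, None, ledger)

    def test_question_with_no_surviving_items_is_removed(self, tiny_questionnaire):
        ledger = DecisionLedger(
            stage=Stage.FINAL_EVALUATION,
            decisions=(
                Decision(target="q3.1", action=Action.DROP),
                Decision(target="q3.2", action=Action.DROP),
            ),
        )
        out, summary = apply_ledger(tiny_questionnaire, None, ledger)
        assert "q3" not in out.question_ids()
        assert summary.dropped == 2 and out.n_questions == 2

    def test_drop_by_question_id_drops_all_subitems(self, tiny_questionnaire):
        ledger = DecisionLedger(
            stage=Stage.FINAL_EVALUATION,
            decisions=(Decision(target="q3", action=Action.DROP),),
        )
        out, summary = apply_ledger(tiny_questionnaire, None, ledger)
        assert summary.dropped == 2 and "q3" not in out.question_ids()

    def test_modify_changes_text_but_not_counts(self, tiny_questionnaire):
        ledger = DecisionLedger(
            stage=Stage.CONSENSUS_ROUND,
            decisions=(
                Decision(target="q1", action=Action.MODIFY, new_text="Reworded"),
            ),
        )
        out, summary = apply_ledger(tiny_questionnaire, None, ledger)
        assert out.n_items == tiny_questionnaire.n_items
        assert summary.modified == 1 and summary.kept == tiny_questionnaire.n_items
        _, q = out.find_question("q1")
        assert q.text == "Reworded"

    def test_add_question_and_add_item(self, tiny_questionnaire):
        ledger = DecisionLedger(
            stage=Stage.CONSENSUS_ROUND,
            decisions=(
                Decision(
                    action=Action.ADD,
                    part_id="partA",
                    question=Question(
                        question_id="q4", text="New", items=(Item(item_id="q4"),)
                    ),
                ),
                Decision(
                    action=Action.ADD,
                    question_id="q3",
                    item=Item(item_id="q3.3", text="New sub-item"),
                ),
            ),
        )
        out, summary = apply_ledger(tiny_questionnaire, None, ledger)
        assert summary.added == 2
        assert "q4" in out.question_ids() and "q3.3" in out.item_ids()

    def test_two_decisions_for_one_target_rejected(self):
        with pytest.raises(ValueError, match="multiple decisions"):
            DecisionLedger(
                stage=Stage.CONSENSUS_ROUND,
                decisions=(
                    Decision(target="q1", action=Action.KEEP),
                    Decision(target="q1", action=Action.DROP),
                ),
            )


class TestLedgerIO:
    def test_ledger_roundtrip(self, tmp_path):
        ledger = load_consensus_ledger()
        path = tmp_path / "ledger.yaml"
        write_ledger(ledger, path)
        assert read_ledger(path) == ledger


# --- conservation property over random ledgers -----------------------------


@given(st.data())
def test_conservation_holds_for_random_ledgers(data):
    """items_out = kept + promoted + added, dropped = items_in - kept - promoted."""
    v0 = load_initial_questionnaire()
    verdicts = load_initial_verdicts()
    item_ids = list(v0.item_ids())
    actions = data.draw(
        st.lists(
            st.sampled_from([None, Action.KEEP, Action.DROP, Action.PROMOTE]),
            min_size=len(item_ids),
            max_size=len(item_ids),
        )
    )
    decisions = []
    for item_id, action in zip(item_ids, actions):
        if action is None:
            continue
        if action is Action.PROMOTE and verdicts[item_id].status is Status.SELECTED:
            action = Action.KEEP  # promotion is only legal for orange/red items
        decisions.append(Decision(target=item_id, action=action))
    ledger = DecisionLedger(stage=Stage.CONSENSUS_ROUND, decisions=tuple(decisions))
    try:
        out, summary = apply_ledger(v0, verdicts, ledger)
    except LedgerError:
        # the random draw may empty the questionnaire entirely
        return
    assert summary.conserved()
    assert out.n_items == summary.kept + summary.promoted + summary.added
    assert summary.dropped == v0.n_items - summary.kept - summary.promoted
    assert all(len(q.items) >= 1 for _, q in out.iter_questions())
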