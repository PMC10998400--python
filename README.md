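# delphikit

Analysis toolkit for **RAND-modified Delphi** expert-panel studies — the
consensus method used to develop and content-validate questionnaires
(here: a process-evaluation questionnaire for automated audit & feedback
systems in primary care) by combining individual expert rating rounds
with a face-to-face consensus meeting under predefined quantitative
selection rules.

It is written for health-services researchers running such a panel:
it ingests the panel's ratings and rankings, applies the selection
rules, produces the per-expert feedback reports used between rounds,
and keeps an auditable ledger of every keep/drop/promote/add decision
that carries one questionnaire version into the next.

## The method

A panel of *n* experts rates every questionnaire item on a 9-point
Likert relevance scale (1 = not relevant, 9 = highly relevant, with an
explicit *not evaluable* option) and ranks each section's questions in
a top-3 or top-5. Three statistics summarize each item:

- **median** of the evaluable scores;
- **tertile fractions** — the share of scores in 1–3 / 4–6 / 7–9;
- **prioritization (top) percentage** — rank *r* in a top-*k* list
  earns *k − r + 1* points; the top percentage is
  `100 × Σ points / (n × k)`. For example, if 10 of 14 panelists rank a
  question first in a top-5 and 4 omit it, it scores
  `50 / (14 × 5) = 71.4 %`.

Two rules triage each item:

| Preselection                          | outcome      |
|---------------------------------------|--------------|
| median ≥ 7 and top ≥ 20 %             | selection    |
| median ≥ 7 and 0 % < top < 20 %       | discussion   |
| median < 7 and top ≥ 20 %             | discussion   |
| otherwise                             | no selection |

| Consensus                                         | outcome      |
|---------------------------------------------------|--------------|
| ≥ 70 % of scores in the highest tertile           | consensus    |
| ≥ 30 % in the highest **and** ≥ 30 % in the lowest | discussion  |
| otherwise                                         | no consensus |

An item is **selected** (green) when both rules return their top
category, **not selected** (red) when both return their bottom
category, and **up for discussion** (orange) otherwise. The consensus
meeting may override the triage; its decisions are recorded as an
explicit ledger and replayed to produce the next questionnaire version.

## Worked example

Generate a synthetic 14-member panel rating 57 items under 34 questions
(the package ships a seeded generator because raw panel ratings of such
studies are not published), score it, and render the feedback reports:

```bash
delphikit simulate --seed 42 --out sim
# panelists: 14  questions: 34  items: 57
delphikit score --questionnaire sim/questionnaire.yaml \
  --ratings sim/ratings.csv --rankings sim/rankings.csv \
  --panel-size 14 --out res
# selected: 22  up_for_discussion: 25  not_selected: 10
delphikit feedback --questionnaire sim/questionnaire.yaml \
  --ratings sim/ratings.csv --rankings sim/rankings.csv \
  --panel-size 14 --seed 42 --out fb
# reports: 14
```

`res/results.csv` holds one row per item:

```
item_id,n_evaluable,median,frac_low,frac_mid,frac_high,top_pct,preselection,consensus,status
1,14,8.000000,0.000000,0.142857,0.857143,37.142857,selection,consensus,selected
2,14,8.500000,0.071429,0.000000,0.928571,51.428571,selection,consensus,selected
```

Item 1 was rated evaluable by all 14 panelists, has median 8 with 86 %
of scores in the highest tertile and a top percentage of 37 % — both
rules return their top category, so the item is selected (green). The
status counts (22 / 25 / 10) reflect the mixed profile assignment of
the generator: half the synthetic questions are drawn agreeable, the
rest lukewarm, polarized or irrelevant.

The same pipeline replays the shipped development-chain fixtures — a
57-item draft triaged 34 / 16 / 7, a consensus meeting keeping 31 of
the 34 selected items, promoting 10 + 2 after rewording and adding one
question (→ 44 items over 31 questions), and a final evaluation
dropping one question (→ 43 items over 30 questions):

```python
from delphikit.datasets import development_chain
versions, ledgers, summaries = development_chain()
[(v.n_items, v.n_questions) for v in versions]
# [(57, 34), (44, 31), (43, 30)]
```

## Layout

| module                      | contents                                             |
|-----------------------------|------------------------------------------------------|
| `delphikit.panel_data`      | domain types + CSV/YAML I/O, NE vs missing semantics |
| `delphikit.scoring`         | median, tertile fractions, prioritization percentage |
| `delphikit.selection`       | preselection/consensus rules, thresholds, triage     |
| `delphikit.feedback`        | per-expert markdown feedback reports                 |
| `delphikit.rounds`          | decision ledgers, version transforms, audit trail    |
| `delphikit.synthetic_panel` | seeded panel generator + profile-recovery experiment |
| `delphikit.datasets`        | shipped development-chain and final-instrument fixtures |
| `delphikit.cli`             | `delphikit {simulate,score,feedback,apply,audit}`    |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
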