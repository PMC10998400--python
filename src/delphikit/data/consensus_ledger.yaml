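stage: consensus_round
decisions:
- target: '4'
  action: keep
  rationale: ''
- target: '5'
  action: keep
  rationale: ''
- target: '6'
  action: keep
  rationale: ''
- target: '10'
  action: keep
  rationale: ''
- target: '12.1'
  action: keep
  rationale: ''
- target: '12.2'
  action: keep
  rationale: ''
- target: '12.3'
  action: keep
  rationale: ''
- target: '13'
  action: keep
  rationale: ''
- target: '14.1'
  action: keep
  rationale: ''
- target: '14.3'
  action: keep
  rationale: ''
- target: '15'
  action: keep
  rationale: ''
- target: '16'
  action: keep
  rationale: ''
- target: '17'
  action: keep
  rationale: ''
- target: '18'
  action: keep
  rationale: ''
- target: '20'
  action: keep
  rationale: ''
- target: '21.1'
  action: keep
  rationale: ''
- target: '21.2'
  action: keep
  rationale: ''
- target: '22'
  action: keep
  rationale: ''
- target: '23.1'
  action: keep
  rationale: ''
- target: '23.2'
  action: keep
  rationale: ''
- target: '23.3'
  action: keep
  rationale: ''
- target: '23.4'
  action: keep
  rationale: ''
- target: '23.6'
  action: keep
  rationale: ''
- target: '25'
  action: keep
  rationale: ''
- target: '26'
  action: keep
  rationale: ''
- target: '27.1'
  action: keep
  rationale: ''
- target: '27.3'
  action: keep
  rationale: ''
- target: '27.4'
  action: keep
  rationale: ''
- target: '29'
  action: keep
  rationale: ''
- target: '30'
  action: keep
  rationale: ''
- target: '1'
  action: modify
  rationale: reworded by the panel during the consensus meeting
  new_text: What role do you assume as a caregiver? (extended to all primary-care
    disciplines)
- target: '27.9'
  action: drop
  rationale: dropped by the panel despite round-1 selection
- target: '28'
  action: drop
  rationale: dropped by the panel despite round-1 selection
- target: '24.2'
  action: drop
  rationale: dropped by the panel despite round-1 selection
- target: '14.2'
  action: drop
  rationale: not retained by the panel
- target: '14.4'
  action: drop
  rationale: not retained by the panel
- target: '14.5'
  action: drop
  rationale: not retained by the panel
- target: '23.5'
  action: drop
  rationale: not retained by the panel
- target: '23.8'
  action: drop
  rationale: not retained by the panel
- target: '24.1'
  action: drop
  rationale: not retained by the panel
- target: '27.6'
  action: drop
  rationale: not retained by the panel
- target: '27.7'
  action: drop
  rationale: not retained by the panel
- target: '27.8'
  action: drop
  rationale: not retained by the panel
- target: '33'
  action: drop
  rationale: not retained by the panel
- target: '34'
  action: drop
  rationale: not retained by the panel
- target: '2'
  action: promote
  rationale: content judged valuable after rewording
- target: '7'
  action: promote
  rationale: content judged valuable after rewording
- target: '8'
  action: promote
  rationale: content judged valuable after rewording
- target: '9'
  action: promote
  rationale: content judged valuable after rewording
- target: '11'
  action: promote
  rationale: content judged valuable after rewording
- target: '19'
  action: promote
  rationale: content judged valuable after rewording
- target: '23.7'
  action: promote
  rationale: content judged valuable after rewording
- target: '27.2'
  action: promote
  rationale: content judged valuable after rewording
- target: '27.5'
  action: promote
  rationale: content judged valuable after rewording
- target: '32'
  action: promote
  rationale: content judged valuable after rewording
- target: '3'
  action: promote
  rationale: content judged valuable after rewording
- target: '31'
  action: promote
  rationale: content judged valuable after rewording
- target: '35'
  action: add
  rationale: new question on the payment system raised at the meeting
  question:
    question_id: '35'
    text: What payment system do you work with?
    response_format: categorical
    items:
    - item_id: '35'
      text: Payment system
      origin: panel_added
  part_id: part1
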