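version_label: round1-draft
provenance: drafting
parts:
- part_id: part1
  title: Section part1
  ranking_depth: 5
  questions:
  - question_id: '1'
    text: Question 1
    response_format: likert_agreement
    items:
    - item_id: '1'
      text: Statement 1
      origin: cp_fit
  - question_id: '2'
    text: Question 2
    response_format: likert_agreement
    items:
    - item_id: '2'
      text: Statement 2
      origin: cp_fit
  - question_id: '3'
    text: Question 3
    response_format: likert_agreement
    items:
    - item_id: '3'
      text: Statement 3
      origin: cp_fit
  - question_id: '4'
    text: Question 4
    response_format: likert_agreement
    items:
    - item_id: '4'
      text: Statement 4
      origin: cp_fit
  - question_id: '5'
    text: Question 5
    response_format: likert_agreement
    items:
    - item_id: '5'
      text: Statement 5
      origin: cp_fit
  - question_id: '6'
    text: Question 6
    response_format: likert_agreement
    items:
    - item_id: '6'
      text: Statement 6
      origin: cp_fit
  - question_id: '7'
    text: Question 7
    response_format: likert_agreement
    items:
    - item_id: '7'
      text: Statement 7
      origin: cp_fit
  - question_id: '8'
    text: Question 8
    response_format: likert_agreement
    items:
    - item_id: '8'
      text: Statement 8
      origin: cp_fit
  - question_id: '9'
    text: Question 9
    response_format: likert_agreement
    items:
    - item_id: '9'
      text: Statement 9
      origin: cp_fit
  - question_id: '10'
    text: Question 10
    response_format: likert_agreement
    items:
    - item_id: '10'
      text: Statement 10
      origin: cp_fit
  - question_id: '11'
    text: Question 11
    response_format: likert_agreement
    items:
    - item_id: '11'
      text: Statement 11
      origin: cp_fit
  - question_id: '12'
    text: Question 12
    response_format: likert_agreement
    items:
    - item_id: '12.1'
      text: Statement 12.1
      origin: reflect52
    - item_id: '12.2'
      text: Statement 12.2
      origin: reflect52
    - item_id: '12.3'
      text: Statement 12.3
      origin: reflect52
- part_id: part2_1
  title: Section part2_1
  ranking_depth: 3
  questions:
  - question_id: '13'
    text: Question 13
    response_format: likert_agreement
    items:
    - item_id: '13'
      text: Statement 13
      origin: cp_fit
  - question_id: '14'
    text: Question 14
    response_format: likert_agreement
    items:
    - item_id: '14.1'
      text: Statement 14.1
      origin: reflect52
    - item_id: '14.2'
      text: Statement 14.2
      origin: reflect52
    - item_id: '14.3'
      text: Statement 14.3
      origin: reflect52
    - item_id: '14.4'
      text: Statement 14.4
      origin: reflect52
    - item_id: '14.5'
      text: Statement 14.5
      origin: reflect52
  - question_id: '15'
    text: Question 15
    response_format: likert_agreement
    items:
    - item_id: '15'
      text: Statement 15
      origin: cp_fit
  - question_id: '16'
    text: Question 16
    response_format: likert_agreement
    items:
    - item_id: '16'
      text: Statement 16
      origin: cp_fit
- part_id: part2_2
  title: Section part2_2
  ranking_depth: 3
  questions:
  - question_id: '17'
    text: Question 17
    response_format: likert_agreement
    items:
    - item_id: '17'
      text: Statement 17
      origin: cp_fit
  - question_id: '18'
    text: Question 18
    response_format: likert_agreement
    items:
    - item_id: '18'
      text: Statement 18
      origin: cp_fit
  - question_id: '19'
    text: Question 19
    response_format: likert_agreement
    items:
    - item_id: '19'
      text: Statement 19
      origin: cp_fit
  - question_id: '20'
    text: Question 20
    response_format: likert_agreement
    items:
    - item_id: '20'
      text: Statement 20
      origin: cp_fit
  - question_id: '21'
    text: Question 21
    response_format: likert_agreement
    items:
    - item_id: '21.1'
      text: Statement 21.1
      origin: reflect52
    - item_id: '21.2'
      text: Statement 21.2
      origin: reflect52
  - question_id: '22'
    text: Question 22
    response_format: likert_agreement
    items:
    - item_id: '22'
      text: Statement 22
      origin: cp_fit
- part_id: part2_3
  title: Section part2_3
  ranking_depth: 5
  questions:
  - question_id: '23'
    text: Question 23
    response_format: likert_agreement
    items:
    - item_id: '23.1'
      text: Statement 23.1
      origin: reflect52
    - item_id: '23.2'
      text: Statement 23.2
      origin: reflect52
    - item_id: '23.3'
      text: Statement 23.3
      origin: reflect52
    - item_id: '23.4'
      text: Statement 23.4
      origin: reflect52
    - item_id: '23.5'
      text: Statement 23.5
      origin: reflect52
    - item_id: '23.6'
      text: Statement 23.6
      origin: reflect52
    - item_id: '23.7'
      text: Statement 23.7
      origin: reflect52
    - item_id: '23.8'
      text: Statement 23.8
      origin: reflect52
  - question_id: '24'
    text: Question 24
    response_format: likert_agreement
    items:
    - item_id: '24.1'
      text: Statement 24.1
      origin: reflect52
    - item_id: '24.2'
      text: Statement 24.2
      origin: reflect52
  - question_id: '25'
    text: Question 25
    response_format: likert_agreement
    items:
    - item_id: '25'
      text: Statement 25
      origin: cp_fit
  - question_id: '26'
    text: Question 26
    response_format: likert_agreement
    items:
    - item_id: '26'
      text: Statement 26
      origin: cp_fit
  - question_id: '27'
    text: Question 27
    response_format: likert_agreement
    items:
    - item_id: '27.1'
      text: Statement 27.1
      origin: reflect52
    - item_id: '27.2'
      text: Statement 27.2
      origin: reflect52
    - item_id: '27.3'
      text: Statement 27.3
      origin: reflect52
    - item_id: '27.4'
      text: Statement 27.4
      origin: reflect52
    - item_id: '27.5'
      text: Statement 27.5
      origin: reflect52
    - item_id: '27.6'
      text: Statement 27.6
      origin: reflect52
    - item_id: '27.7'
      text: Statement 27.7
      origin: reflect52
    - item_id: '27.8'
      text: Statement 27.8
      origin: reflect52
    - item_id: '27.9'
      text: Statement 27.9
      origin: reflect52
  - question_id: '28'
    text: Question 28
    response_format: likert_agreement
    items:
    - item_id: '28'
      text: Statement 28
      origin: cp_fit
  - question_id: '29'
    text: Question 29
    response_format: likert_agreement
    items:
    - item_id: '29'
      text: Statement 29
      origin: cp_fit
- part_id: part2_4
  title: Section part2_4
  ranking_depth: 3
  questions:
  - question_id: '30'
    text: Question 30
    response_format: likert_agreement
    items:
    - item_id: '30'
      text: Statement 30
      origin: cp_fit
  - question_id: '31'
    text: Question 31
    response_format: likert_agreement
    items:
    - item_id: '31'
      text: Statement 31
      origin: cp_fit
  - question_id: '32'
    text: Question 32
    response_format: likert_agreement
    items:
    - item_id: '32'
      text: Statement 32
      origin: cp_fit
  - question_id: '33'
    text: Question 33
    response_format: likert_agreement
    items:
    - item_id: '33'
      text: Statement 33
      origin: cp_fit
  - question_id: '34'
    text: Question 34
    response_format: likert_agreement
    items:
    - item_id: '34'
      text: Statement 34
      origin: cp_fit
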