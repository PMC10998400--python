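stage: final_evaluation
decisions:
- target: '11'
  action: drop
  rationale: 'excluded at the researchers'' request: subjective wording'
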