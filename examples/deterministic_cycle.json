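{
  "name": "negative_feedback_cycle",
  "internal": [
    {"id": "A", "rule": "NOT B"},
    {"id": "B", "rule": "A"}
  ],
  "external": []
}
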