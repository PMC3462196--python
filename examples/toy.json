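{
  "name": "toy",
  "internal": [
    {"id": "A", "rule": "E"},
    {"id": "B", "rule": "A"}
  ],
  "external": [
    {"id": "E", "mode": "stochastic", "symbol": "p"}
  ]
}
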