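{
  "domain": [
    0.0,
    1.0
  ],
  "phases": [
    {
      "fixed": {
        "Start": 0,
        "Bud": 0,
        "SAC": 0
      },
      "interval": [
        0.0,
        0.25
      ],
      "control": {
        "p": {
          "type": "linear",
          "interval": [
            0.0,
            0.25
          ],
          "start": 0.01,
          "end": 0.33666666666666667
        }
      }
    },
    {
      "fixed": {
        "Start": 1,
        "Bud": 0,
        "SAC": 0
      },
      "interval": [
        0.25,
        0.5
      ],
      "control": {
        "p": {
          "type": "constant",
          "interval": [
            0.25,
            0.5
          ],
          "value": 0.01
        }
      }
    },
    {
      "fixed": {
        "Start": 1,
        "Bud": 1,
        "SAC": 0
      },
      "interval": [
        0.5,
        0.75
      ],
      "control": {
        "p": {
          "type": "constant",
          "interval": [
            0.5,
            0.75
          ],
          "value": 0.01
        }
      }
    },
    {
      "fixed": {
        "Start": 1,
        "Bud": 1,
        "SAC": 1
      },
      "interval": [
        0.75,
        1.0
      ],
      "control": {
        "p": {
          "type": "constant",
          "interval": [
            0.75,
            1.0
          ],
          "value": 0.01
        }
      }
    }
  ]
}
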