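{
  "name": "yeast_cell_cycle",
  "internal": [
    {
      "id": "Cln3",
      "rule": "CSS"
    },
    {
      "id": "Whi5",
      "rule": "NOT Start OR NOT (Cln3 OR Cln2)"
    },
    {
      "id": "SMBF",
      "rule": "(Cln3 OR Cln2 OR SMBF) AND NOT Whi5 AND NOT Clb2 AND NOT Cdc14"
    },
    {
      "id": "Cln2",
      "rule": "Start AND SMBF"
    },
    {
      "id": "Clb5",
      "rule": "SMBF AND NOT Sic1 AND NOT Cdc20"
    },
    {
      "id": "Clb2",
      "rule": "(Clb5 OR Clb2 OR Mcm1) AND NOT Sic1 AND NOT Cdh1 AND NOT Cdc20 AND NOT Swe1"
    },
    {
      "id": "Sic1",
      "rule": "(NOT Cln2 AND NOT Clb5 AND NOT Clb2) OR Cdc14"
    },
    {
      "id": "Cdh1",
      "rule": "(NOT Cln2 AND NOT Clb5 AND NOT Clb2) OR Cdc14"
    },
    {
      "id": "Swe1",
      "rule": "NOT Bud"
    },
    {
      "id": "Mcm1",
      "rule": "Clb2"
    },
    {
      "id": "Cdc20",
      "rule": "SAC AND Clb2"
    },
    {
      "id": "Cdc14",
      "rule": "Cdc20"
    },
    {
      "id": "Yhp1",
      "rule": "SMBF"
    }
  ],
  "external": [
    {
      "id": "CSS",
      "mode": "stochastic",
      "symbol": "p"
    },
    {
      "id": "Start",
      "mode": "fixed",
      "value": 0
    },
    {
      "id": "Bud",
      "mode": "fixed",
      "value": 0
    },
    {
      "id": "SAC",
      "mode": "fixed",
      "value": 0
    }
  ]
}
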