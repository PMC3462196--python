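# pbcn — ergodic sets of probabilistic Boolean control networks

`pbcn` analyzes **probabilistic Boolean control networks (PBCNs)**: a family
of synchronous Boolean networks over internal nodes `X_1..X_n`, indexed by
the configurations `v` of binary *external inputs*. At each step one
configuration is drawn — stochastic inputs independently active with
probability `p_i ∈ (0,1)`, fixed inputs clamped — and the corresponding
deterministic update map `f_v` is applied. The resulting Markov chain on
the `2^n` internal states is generally reducible; its **ergodic sets**
(recurrent communicating classes, equivalently the terminal strongly
connected components of the union of the `f_v` graphs) are the stochastic
analogue of Boolean attractors and are interpreted as cellular phenotypes.

For each ergodic set `W` the package computes the stationary distribution
`π` of the restricted chain — the unique solution of

    π · M_W = π,   Σ_s π_s = 1

— **symbolically**, as exact rational functions of the probability symbols
(the chain may be periodic, so the solve is a linear system, never power
iteration). The **activity function** of node `X` is the stationary
expectation of its bit, `a_X(p) = Σ_s π_s(p)·bit_X(s)`, read as the
qualitative activation level of the species. Composing activity functions
with a time-dependent **control function** `c(t) ∈ (0,1)` yields activity
*profiles* in time.

The package bundles a 13-node model of the budding-yeast
(*S. cerevisiae*) cell cycle whose four phases are PBCNs selected by three
checkpoint inputs (Start, Bud, SAC) with the cell-size signal CSS as the
single stochastic input driving Cln3. It reproduces, from the network
logic alone: one ergodic set per phase; oscillating cyclin waves opposed by
the CKI Sic1 over the composed cycle; constancy (p-independence) of the
Cln2/Clb5/Clb2 activities during G1–G2/M; the irreversibility of Start via
the Whi5–SMBF–Cln2 positive feedback loop (and its reversibility when the
loop is cut); and completion of one division round with G1 arrest under
nitrogen deprivation (CSS dropped to 0.01 after Start).

## Worked example

The two-node toy network `A' = E`, `B' = A` with one stochastic input `E`:

```bash
$ pbcn classes examples/toy.json
ES1 (size 4, period 1): 1 2 3 4

$ pbcn activity examples/toy.json --symbolic
ES1 (size 4):
  A	p
  B	p
```

All four states form one ergodic set; in stationarity `A` and `B` are
independent Bernoulli(p) bits (each equals the external draw one or two
steps back), so `π(ab) = p^(a+b)(1-p)^(2-a-b)` and both activities are `p`.

The yeast phase analysis:

```bash
$ pbcn yeast phases | python -m json.tool --compact | head -3
```

reports, for each of the four checkpoint configurations, exactly one
ergodic set (sizes 2, 2, 4 and 32 of the 8192 states) with signatures
G1: Sic1/Whi5/Cdh1 active, cyclins inactive; G1/S: Cln2/Clb5 active, Sic1
and Whi5 off; G2/M: Clb2 active; M/G1: everything p-dependent — e.g.

    a_Cln2(p) = (3p² + 2p)/(4p² + 4p + 1),   a_Sic1(p) = (p+1)²/(4p² + 4p + 1)

so as the size signal collapses at the end of mitosis (`p → 0`) the
cyclins deactivate and the CKIs recover toward 1: the cell re-enters G1.

```bash
$ pbcn yeast cycle --out yeast_cycle.tsv     # whole-cycle profile, TSV
$ pbcn yeast cycle --nitrogen --out nd.tsv   # nitrogen-deprivation variant
$ pbcn yeast reversibility                   # cut the Whi5-SMBF-Cln2 loop
```

The reversibility report shows the intact G1/S network pinning
`a_Whi5 = 0`, `a_Cln2 = 1` (constants — Start is committed), while after
removing Cln2 from Whi5's rule the single ergodic set has
`a_Whi5 = 1 - p` and `a_Cln2 = p²(p² - 2p + 2)/(p² - p + 1)`: lowering the
size signal now deactivates Cln2 and reactivates Whi5 — Start has become
reversible.

## Network JSON dialect

```json
{
  "name": "toy",
  "internal": [
    {"id": "A", "rule": "E"},
    {"id": "B", "regulators": ["A"], "table": [0, 1]}
  ],
  "external": [
    {"id": "E", "mode": "stochastic", "symbol": "p"},
    {"id": "S", "mode": "fixed", "value": 0}
  ]
}
```

Rules are expressions over `AND`, `OR`, `NOT`, parentheses, `0`, `1` and
identifiers (keywords case-insensitive), or explicit truth tables over a
declared regulator list (first regulator = most significant bit). State
indices encode the internal nodes with node 1 as the most significant bit;
printed labels are the binary number plus one. Control schedules are JSON
too — see `examples/css_default.json`.
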