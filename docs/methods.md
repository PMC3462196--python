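# Methods

## Model

A PBCN is specified by internal nodes `X_1..X_n` with one Boolean update
rule each, and external inputs that occur in rules but have no rules of
their own. External inputs are *fixed* (clamped to 0/1) or *stochastic*
(active with probability `p_i`, drawn independently every step). Each
external configuration `v` defines a deterministic synchronous update map
`f_v` on the `2^n` internal states; the chain applies a freshly drawn map
each step, so its transition matrix is

    M(p) = Σ_v P(v) · M_{f_v},    P(v) = Π_i p_i^{v_i} (1 - p_i)^{1-v_i}.

Assumptions built into this construction:

* **Synchronous update only.** One configuration is drawn per step and all
  rules fire simultaneously. Asynchronous or generalized update schemes
  are out of scope.
* **Independent stochastic inputs.** `P(v)` is the product form above; no
  joint distribution over inputs is modeled.
* **Open-interval probabilities.** Every `p_i` must lie strictly inside
  (0,1). At a boundary some maps drop out of the generating semigroup and
  the recurrent structure can change discontinuously, so boundary values
  are rejected rather than clamped.
* **No perturbation noise.** Random bit flips would make the whole state
  space one ergodic set and erase the structure this package exists to
  compute.

Because every `P(v)` is positive on the open cube, the support of `M(p)`
is probability-independent: the recurrent communicating classes are
determined by the semigroup generated by the maps alone. They are computed
exactly as the terminal strongly connected components of the union graph
(edge `s -> s'` iff some `f_v(s) = s'`), via a linear-time SCC pass
(`scipy.sparse.csgraph`) and condensation-sink selection. Classes are
ordered by smallest member index and named ES1, ES2, …
`verify_probability_invariance` re-derives the classes from numerically
evaluated matrices at random interior probabilities as a cross-check.

The restricted chain on a class is irreducible but possibly periodic, so
the stationary distribution is obtained by an exact linear solve of
`π(M_W - I) = 0` with one redundant balance equation replaced by the
normalization row — never by power iteration. Symbolically the system is
solved over the rational-function field `QQ(p_1,…,p_m)` using sympy's
`DomainMatrix` LU solve; results are `cancel()`-normalized so equality
tests are cross-multiplications of polynomials, not float comparisons.
The period of each class (gcd of BFS-level differences over internal
edges) is reported for information but gates nothing.

Activity functions `a_X(p) = Σ_s π_s(p)·bit_X(s)` are simplified
rational functions; "constant" means every partial derivative is
identically zero — an exact symbolic statement, not a numeric tolerance.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `max_internal` | 22 | state-space cap (`2^22` states); exceeding it is an explicit error, configurable per call |
| `symbolic_threshold` | 64 | largest class solved symbolically; larger classes switch to per-point numeric solves |
| `num_points` | 1000 | time-grid resolution of composed activity profiles |
| `eps` | 0.01 | clamp of the yeast CSS control to `[eps, 1-eps]` |

For classes above `symbolic_threshold` the restricted system is solved in
floating point at each requested probability vector (dense LU; classes of
a few hundred states solve in microseconds). This is exact at every
evaluated point, so no interpolation layer is used; such results are
flagged `numeric` in the table metadata and reports. All yeast classes
(sizes 2, 2, 4, 32, and 42 for the feedback-removed G1/S network) are
under the threshold, so the shipped analyses are fully symbolic.

## The yeast fixture

The 13 internal nodes are Cln3, Whi5, SMBF (SBF/MBF), Cln2 (Cln1,2), Clb5
(Clb5,6), Clb2 (Clb1,2), Sic1, Cdh1, Swe1, Mcm1, Cdc20, Cdc14 and Yhp1
(YHP1/YOX1); the externals are the stochastic cell-size signal CSS
(symbol `p`, driving Cln3) and the checkpoints Start, Bud, SAC. Checkpoint
logic is wired as clamping terms inside the affected rules, so switching
phases never edits rule structure:

* `Start = 0` forces Whi5 active and Cln2 inactive (pre-Start G1 cells
  cannot fire the G1/S transcription program);
* `Bud = 1` forces Swe1 inactive (degradation at the formed bud neck);
* `SAC = 0` forces Cdc20 inactive (anaphase held until the spindle
  checkpoint is satisfied).

The rule set (see `pbcn.yeast.YEAST_RULES`) encodes the standard
qualitative circuitry: the Whi5 ⊣ SMBF → Cln2 ⊣ Whi5 positive feedback
around Start; Sic1/Cdh1 antagonism against the Clb cyclins with recovery
driven by Cdc14; the mitotic cascade Clb5 → Clb2 → Cdc20 → Cdc14; and
Swe1 inhibition of Clb2 before budding. Two choices deserve comment
because the qualitative literature narrative underdetermines them:

1. **SMBF needs an activator.** `SMBF' = (Cln3 OR Cln2 OR SMBF) AND NOT
   Whi5 AND NOT Clb2 AND NOT Cdc14`. Plain derepression (`NOT Whi5 AND NOT
   Clb2`) admits a synchronous-update artifact: the three-node feedback
   ring falls into a spurious 3-cycle in which SMBF switches on purely
   because Whi5 is momentarily off, and the M/G1 network then never
   reaches its G1-like reset state. Requiring an activating cyclin (or
   persistence of SMBF itself) removes the artifact and matches the
   biology of SBF activation by Cln3.
2. **Cdc14 represses SMBF.** At mitotic exit the phosphatase resets the
   G1 transcription program one step ahead of Whi5 re-entering the
   nucleus; without this edge the reset again misses the G1-like state by
   one synchronous step. This coarse-grains a Whi5-mediated mechanism
   into a direct edge, at the model's one-node-per-module granularity.

With these rules every phase PBCN has exactly one ergodic set (sizes 2, 2,
4, 32), which is the model's robustness statement: there is no competing
attractor, so any internal perturbation returns to the phase's ergodic
set. The feedback-removal experiment clamps Cln2 to 0 inside Whi5's rule
(the loop edge into Whi5); the exact edge to cut is not uniquely
determined by the phenotype, but this choice reproduces it: the single
ergodic set of the modified G1/S network has `a_Whi5 = 1 - p` and
`a_Cln2 = p²(p² - 2p + 2)/(p² - p + 1)`, both monotone, with Cln2 → 0 and
Whi5 → 1 as `p → 0`.

## Control schedules

The yeast cycle occupies the unit interval, one quarter per phase, with
checkpoints activated cumulatively: (0,0,0), (1,0,0), (1,1,0), (1,1,1).
The printed sources constrain the CSS control only qualitatively (grow for
most of the cycle, peak when the spindle checkpoint is satisfied, drop at
the end), so the default is the simplest compliant shape: a linear ramp
0.01 → 0.99 on [0, 3/4] and 0.99 → 0.01 on [3/4, 1]. The nitrogen
variant keeps the same rising slope during G1 and holds 0.01 afterwards.
The composed profiles in phases 1–3 are provably independent of the ramp's
shape wherever the activity functions are constant (which covers the key
cyclins), and the test suite checks this with a kinked alternative ramp.
Phase boundaries are evaluated from within the *later* phase
(right-continuity): a phase switch is a model switch, not a limit.

## Simulation oracle

`walk` draws each stochastic input per step (inverse-CDF on a
`numpy` Generator) and applies the selected map; per-walk streams derive
from `(master seed, walk index)` via `SeedSequence.spawn`, so all results
are machine-independent. `absorption_census` classifies a walk by its last
`4·|largest class|` states. `monte_carlo_check` compares post-burn-in
state frequencies with the analytic stationary law (L1 distance); the test
suite requires L1 < 0.01 at 200 000 steps for the closed-form toy network,
about three times the binomial sampling bound at that length.

## Synthetic networks

`random_network(n, m_s, rng)` draws, for each node, 1–3 regulators
uniformly from the internal nodes plus externals and a uniform random
truth table. These networks exercise the analytic layer across reducible
chains with many classes, deterministic limits (`m_s = 0`) and multiple
stochastic inputs. They emulate none of the structure of curated
biological models (canalization, scale-free wiring, functional coherence),
so passing the property suite shows correctness of the mathematics, not
biological plausibility — the yeast fixture carries that weight.

## Numerical choices and degenerate inputs

* Row-stochasticity and `π M = π` are asserted as polynomial identities
  after `cancel()`, with floats entering only at explicit evaluation.
* Numeric row sums are checked to 1e-12; symbolic/numeric agreement of
  stationary laws to 1e-10 (both well above double-precision LU error for
  these sizes).
* Probabilities and control values exactly on {0, 1} raise; the CSS clamp
  `eps = 0.01` keeps the bundled schedules inside the open interval.
* A state set that is not closed under the matrix, or whose restricted
  system is singular (not irreducible), raises instead of returning a
  pseudo-distribution.
* Problem sizes used in the shipped analyses: 8192-state phase networks,
  classes ≤ 42 states solved symbolically in about a second; the
  acceptance run and the full test suite complete in well under a minute.

## Known limitations

* Synchronous semantics only; no SBML-qual import; no perturbation-PBN
  mode (deliberately, see above).
* Basin sizes of ergodic sets are not defined for PBCNs (a walk from one
  state may reach different classes), so no basin-based robustness metric
  is offered; `absorption_census` gives the empirical analogue.
* Symbolic solves scale with class size, not state-space size; classes
  beyond a few hundred states should use the numeric path.
* The yeast rule set is a qualitative transcription at one-node-per-module
  granularity; it is validated against the phase phenotypes it is meant to
  reproduce, not against kinetic data.
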