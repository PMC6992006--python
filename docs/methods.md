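# Methods

## Model

`egalnorm` simulates a population of `N` agents on a network (complete graph
by default) playing the continuous Ultimatum Game. Agent `i` carries an
individual norm `IN_i = [p_i, q_i]` with both components in `[0, 0.5]`:
`p_i` is the fraction offered when proposing, `q_i` the minimum fraction
accepted when responding. An offer succeeds iff `p ≥ q` (Heaviside acceptance
with ties accepted, `H(0) = 1`; this is load-bearing — a self-compatible
agent always agrees with a copy of itself, and boundary norms such as
`[0, 0]` are viable).

Each time step has two (optionally three) phases:

1. **Interaction.** Every connected pair plays two deals, one per proposer
   role. The resource carried by each deal is set by *resource management*:
   both parties shift resources toward the deal that succeeded last round,

       R_i = 1 + Δ·(S_ij − S_ji),   R_j = 2 − R_i,

   where `S_ij ∈ {0, 1}` is last round's outcome of the deal with `i`
   proposing. `Δ ∈ [0, 1]` is the management intensity; the pair total
   `R_i + R_j = 2` is conserved, so the maximal population payoff is
   independent of Δ. The payoff of `i` from `j` is
   `P(IN_i, IN_j) = (1 − p_i)·H(p_i − q_j)·R_i + p_j·H(p_j − q_i)·R_j`,
   and the agent's fitness is the mean of `P` over its neighbourhood.
   Per-pair deal memory (the *deal ledger*) is one round deep and starts
   all-successful, which makes every initial resource exactly 1.

2. **Norm update (synchronous).** With probability `μ` an agent explores
   (fresh norm uniform on `[0, 0.5]²`); otherwise it picks one neighbour
   uniformly at random and imitates its norm with the Fermi probability
   `T(ΔP) = 1/(1 + exp(−ΔP/K))`. Imitated components receive i.i.d. uniform
   learning error on `[−ε, ε]` and are clipped back into `[0, 0.5]`. All
   role models are read from the pre-update generation.

3. **Trait coevolution (optional).** When the time-scale ratio `s > 0`, the
   per-agent intensity `Δ_i` evolves by `round(s·N)` sequential
   pairwise-comparison micro-steps after each norm update: a random agent
   copies a random neighbour's `Δ` with the Fermi probability computed from
   the last interaction phase's payoffs, plus a uniform perturbation on
   `[−0.025, 0.025]`, clipped to `[0, 1]`. A pair with unequal traits uses
   `Δ = min(Δ_i, Δ_j)` — the most conservative choice, and the least
   favourable for the trait's spread. Coevolution runs start from
   `Δ_i = 0` everywhere.

Observables: fairness `p̄, q̄` (population means), empathy
`ē = mean(1 − |p_i − q_i|/0.5)`, and collective conformity
`c̄ = mean(1 − ‖(p_i, q_i) − (p̄, q̄)‖/(√2/2))`, all in `[0, 1]` (conformity
uses the same-step means; that is the only self-consistent reading of the
definition). Equilibrium values are arithmetic means over a recorded window
after a transient.

## Mean-field companion

The two-norm reduction keeps an egalitarian self-compatible norm
`IN₂ = [p₂, q₂]` and a less generous `IN₁ = [p₁, q₁]`. When `p₁ < q₂`
(the conflict ordering) the mixed pair has a persistent one-sided conflict
and the stationary payoff matrix is `a = d = 1`, `b = (1 − p₂)(1 + Δ)`,
`c = p₂(1 + Δ)`; in the other two orderings every deal succeeds and Δ
cancels. Entries are stationary per-round pair payoffs, i.e. after one round
of ledger burn-in — the first round (all resources 1) differs, which the
simulator tests verify directly. Replicator dynamics
`ẋ = x(1−x)[(a−c)x + (b−d)(1−x)]` for the frequency `x` of `IN₂` give:
bistability with unstable point `x* = (d−b)/(a−b−c+d)` and egalitarian basin
`1 − x* = 1 − p₂ > 1/2` at `Δ = 0` (risk dominance), growing with Δ, and
complete dominance once `Δ ≥ Δ* = p₂/(1 − p₂)`. At `p₂ = 1/2` dominance is
unattainable (a draw at best), which is why the population never reaches the
fully egalitarian corner. The closed-form classification is cross-checked
against fixed-step RK4 forward integration (step 0.01, absorbing tolerance
1e-9 at the boundaries; the separatrix located by bisection on the ODE fate
agrees with `x*` to 1e-6).

## Parameters and defaults

| parameter | meaning | default | notes |
|---|---|---|---|
| `Δ` | resource-management intensity | 1.0 | `[0, 1]`; 0 disables management |
| `μ` | exploration rate | 0 | reference dynamics are pure imitation |
| `K` | Fermi selection noise | 0.1 | payoff scale is O(1) per pair |
| `ε` | learning-error half-range | 5·10⁻³ | keeps norms effectively continuous |
| `s` | trait/norm time-scale ratio | 0 (off); 0.1 in coevolution runs | `s·N` micro-steps per step |
| `N` | population size | 500 | desk-scale default, see below |
| horizon | time steps | 5000 | desk-scale default |
| window | equilibrium averaging | final half of the run | arithmetic mean |

Out-of-range perturbed values (norms and Δ) are **clipped**, not reflected or
re-drawn — the simplest rule consistent with the hard intervals. Exploration
draws use the initialization distribution (uniform on `[0, 0.5]²`). The deal
ledger persists when an agent changes norm: memory attaches to the pair, not
the norm. Isolated nodes keep payoff 0 rather than raising.

All randomness flows through one `numpy` Generator seeded from the run
config, so identical config + seed gives byte-identical output files.

## Study conditions and scaling

The reference conditions are a complete graph with norms initialized i.i.d.
uniform on `[0, 0.5]²`, `μ = 0`, `K = 0.1`, `ε = 5·10⁻³`, and unit initial
resources. A fresh population then has `p̄ ≈ q̄ ≈ 0.25`, `ē ≈ 2/3` (the exact
expectation of `1 − 2|p − q|` for independent uniforms) and `c̄ ≈ 0.729`
(one minus the mean distance to the square's centre over its half-diagonal).

The package's default problem size is `N = 500` for 5000 steps with the
final half as the equilibrium window, averaged over 10 independent seeds in
the acceptance script — a desk-scale protocol chosen so a full reproduction
runs in minutes on one core. The reference large-scale behaviour is defined
at `N = 10⁴` with equilibrium averaging over millions of steps; that scale
changes the *quantitative* equilibrium of the managed (`Δ = 1`) regime
substantially, see Limitations.

## What the scaled-down runs do and do not show

At `Δ = 0` the scaled-down equilibrium is insensitive to `N`: runs collapse
to a selfish, empathetic, conformist state (`p̄ ≈ 0.06`, `q̄ ≈ 0.02`,
`ē ≈ 0.92`, `c̄ ≈ 0.98`), matching the large-scale reference values closely.

At `Δ = 1` the egalitarian state (`p̄ ≈ 0.31–0.36`, `ē ≈ 0.87+`, `c̄ ≈ 0.96`)
is reached, but at `N = 500` it is *metastable*: demographic noise
intermittently triggers invasions of self-incompatible "spiteful rejecter"
norms (high `q`, moderate `p`), which profit transiently because rejecting a
partner's offer doubles the resource behind one's own next proposal
(`R = 1 + Δ`). These norms score zero against each other, so the excursions
collapse and the fair state re-forms — the time series switches between the
fair phase and a disordered high-rejection phase on a 10³–10⁴-step scale.
The switching persists at least up to `N = 4000` in our experiments, so
*time-averaged* fairness and empathy in the managed regime sit well below
the fair-phase (snapshot) values at every desk-reachable size, with a wide
across-seed spread. Reference values quoted at a single large-`N` time point
should therefore be read as fair-phase levels — which the simulator
reproduces (`p̄ ≈ 0.31`, `ē ≈ 0.87`, `c̄ ≈ 0.96` within fair-phase windows) —
rather than as long-run window averages. The coevolution run shares this
caveat and is additionally far from trait-stationary after 5000 steps
(`Δ̄` is still growing ≈0.14 → ≈0.43 between t = 5·10³ and 2·10⁴). The
qualitative regime separation (managed fair vs unmanaged selfish) is robust
across every seed tested.

## Numerical choices

- Complete graphs use a dense `O(N²)` vectorized interaction kernel with
  preallocated buffers; arbitrary edge lists use a per-edge vectorized path
  with `bincount` accumulation. Both paths implement the identical contract
  and are cross-checked against each other in the tests.
- Fermi probabilities are computed with `scipy.special.expit` (vectorized,
  saturation-safe).
- The coevolution micro-step loop is sequential by construction (later
  micro-steps must see earlier Δ copies); its random draws are pre-generated
  per phase for speed.
- Micro-step count `s·N` is rounded to the nearest integer.
- Replicator integration: fixed-step RK4, `dt = 0.01`, absorbing tolerance
  `1e-9`, horizon 600 time units — ample for escape from any tested
  separatrix at the rates involved.

## Limitations

- One-round deal memory only; longer memories are out of scope.
- The resource-management procedure itself is error-free.
- Scaled-down quantitative equilibria for the managed regime depend on `N`
  (see above); the package reports what its own study conditions produce and
  does not extrapolate to larger populations.
- Synchronous updating and the Fermi rule are fixed; asynchronous or
  alternative imitation dynamics are not implemented.
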