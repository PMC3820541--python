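# Methods

## Model

The relay has four layers — histidine kinase (HK), receiver (REC),
phosphotransfer protein (Hpt), response regulator (RR) — each present in a
phosphorylated and an unphosphorylated form with a conserved per-layer
total. Reactions (mass action):

- autophosphorylation `HK → HK~P` at rate `k_s` (the signal),
- forward transfers `HK~P + REC → HK + REC~P` (`k_2`),
  `REC~P + Hpt → REC + Hpt~P` (`k_3`), `Hpt~P + RR → Hpt + RR~P` (`k_4`),
- reverse transfers with rate constants `k_2r`, `k_3r`, `k_4r`,
- hydrolysis `REC~P → REC` (`k_h1`) and `RR~P → RR` (`k_h2`), reflecting
  the instability of phospho-aspartate (HK and Hpt carry phospho-histidine
  and are stable in the base model).

Units are arbitrary but coherent (concentration, time); bimolecular rate
constants carry concentration⁻¹·time⁻¹. A topology is the subset of the
three reverse transfers and two hydrolyses that are present (2⁵ = 32).
Topology ids follow the standard block convention: ids 1–8 carry
hydrolysis code (0,1), 9–16 (1,0), 17–24 (0,0), 25–32 (1,1), with
within-block reverse codes in the order (100), (010), (001), (101), (110),
(011), (000), (111). This assignment is verified at import time against
the 18 reference id↔code pairs for the responsive topologies; the ordering of
the 14 non-responsive ids follows the same rule but has no independent
cross-check.

## Steady-state elimination

At steady state the net transfer flux through each layer balances the
losses below it, so, moving bottom-up with the output `rr = [RR~P]` as the
free variable:

1. `k_4·Hpt~P·(RR_tot − rr) − k_4r·rr·(Hpt_tot − Hpt~P) = k_h2·rr`
   (linear in Hpt~P),
2. `k_3·REC~P·(Hpt_tot − Hpt~P) − k_3r·(REC_tot − REC~P)·Hpt~P = k_h2·rr`
   (linear in REC~P),
3. `k_2·HK~P·(REC_tot − REC~P) − k_2r·(HK_tot − HK~P)·REC~P
   = k_h2·rr + k_h1·REC~P` (linear in HK~P),
4. `k_s = (k_h2·rr + k_h1·REC~P) / (HK_tot − HK~P)`.

This defines the signal function `k_s = f(rr)`, strictly increasing on its
feasible domain `[0, α)` and divergent at α, the maximal response. α is
located by bisection on the feasibility of the chain (every intermediate
within `[0, total]`, positive denominators) between 0 and `RR_tot`, to
relative tolerance 1e-10 of `RR_tot`. The bisection is the operational
version of "the first positive root of the denominator polynomial": the
chain becomes infeasible exactly where the domain of f ends. Curves are
sampled on the grid `0, α/100, …, 0.95 α` (96 points, zero included).

A topology is non-responsive — its output saturates at any positive
signal — iff RR~P is not hydrolyzed (`h2 = 0`) and, additionally, REC~P is
not hydrolyzed or one of the two lower reverse transfers is missing. Of
the 32 topologies, 14 are non-responsive. A numerical screen (ODE steady
states at signals 1e-6 and 1 with all present rates and totals set to 1;
responsive iff the outputs differ by more than 1% of total RR) agrees with
the structural predicate on all 32 topologies and is insensitive to
re-drawing the generic rates.

## Derivatives and classification

Derivatives of f are computed by second-order forward-mode jets propagated
through the elimination (exact to machine precision; no differencing of ODE
output). The curvature of the response curve at zero signal is
`R''(0) = −f''(0)/f'(0)³`.

- **Classification 1** (default): sigmoidal iff `R''(0) > 0`.
- **Classification 2**: `R''` is evaluated at 200 points along the curve's
  own sampling grid (uniform in response up to `0.95 α`); sigmoidal iff a
  run of at least two consecutive positive values is followed by a run of
  at least two negative values. The run rule suppresses isolated numerical
  sign flips; the response-uniform grid resolves narrow convex onsets that
  a signal-uniform grid misses. The two classifications agree on ≥ 98% of
  sampled instances per topology; residual disagreements are borderline
  curves whose convex onset is thinner than the grid.

Necessary conditions for sigmoidality (all strict): `k_h1 > 0`,
`k_2 > k_2r`, and `k_3r > k_3` or `k_3r·k_4r > k_3·k_4` (hence
`k_3r > 0`). The third condition is the contrapositive of the
curvature-sign implication "if `k_3 > k_3r` and `k_3·k_4 > k_3r·k_4r` the
curve is hyperbolic". An additive variant of the third condition
(`k_3r + k_4r > k_3 + k_4`) is strictly weaker in practice: across 54,000
classified draws it is violated by a small set of genuinely sigmoidal
instances (strong `k_4r` dominance with moderate `k_3r`), while the
product form has no violations; the product form is therefore the one
implemented.

The Hill coefficient is `n_H = log 81 / log(input90/input10)` with the two
signals obtained by monotone (PCHIP) interpolation of the curve at 10% and
90% of α; a Michaelis–Menten curve gives exactly 1, a Hill-exponent-2 curve
exactly 2.

## Parameter sampling and surveys

The sampler draws, per set: the six bimolecular constants log-uniform on
[1e-2, 1e2] (forward and reverse i.i.d., so ratio-based conditions are
scale-free), the two hydrolysis constants log-uniform on [1e-3, 1e1], and
totals log-uniform on [1e-1, 1e1] — one shared value in `equal` mode (the
headline-table convention) or four independent values in `free` mode.
Rates absent from the topology are zeroed after drawing, keeping the
stream aligned across topologies. Defaults: 1000 sets per topology,
classification 1, percentages reported to two decimals. All draws are
deterministic given the seed; survey artifacts are byte-identical across
runs.

These ranges are a broad, symmetric "permissible regime" chosen for
scale-freeness, not a fit to measured kinetic constants. Quantities that
are structural (forced-zero topologies, necessity of the analytic
conditions, which topologies lead) are insensitive to them; exact
fraction values and some distributional contrasts (regime-resolved response
times, arithmetic-mean rate ratios, the exact membership of the ">2%
sigmoidal" set) are range-dependent, and under these symmetric ranges six
rather than four topologies exceed the 2% mark (26 and 29 join 14, 16, 30,
32; topologies 14 and 30 still lead by a wide margin with near-even regime
splits). Rate-ratio summaries therefore report median and geometric mean
alongside the arithmetic mean, which four-decade sampling makes
outlier-dominated.

## Intrinsic noise (CTMC)

With equal layer totals T and `g = N/T` molecules per concentration unit,
the relay at small copy number is a continuous-time Markov chain on the
lattice of phospho-counts `(n_HK~P, n_REC~P, n_Hpt~P, n_RR~P) ∈ {0..N}⁴`
(N = 10 by default → 14,641 states). Bimolecular propensities use `k/g`;
unimolecular rates are unchanged. Only reaction-event stochasticity is
modeled — parameters do not fluctuate.

The stationary distribution is computed exactly on the closed communicating
class (strong connectivity on the generator's graph): one balance equation
is replaced by pinning the probability of a reference state, and the
resulting sparse system is solved directly (small lattices) or by
ILU-preconditioned LGMRES. The pinned state is the lattice point nearest
the deterministic steady state — pinning a high-probability state keeps the
unknown probability ratios moderate; pinning the empty corner makes the
system numerically intractable at saturating signals. A uniformization
power iteration serves as a factorization-free fallback and as the solver
for larger lattices (N = 20, 194,481 states). A direct-method Gillespie
simulator cross-checks stationary moments (time averages past a burn-in).

Regime comparisons use matched pairs: one random draw yields both members,
with the lower-layer forward/reverse pairs oriented reverse-dominant
(sigmoidal-leaning) or forward-dominant (hyperbolic-leaning) and all
magnitudes shared; a pair is kept only if the two members actually classify
sigmoidal and hyperbolic. Noise (SD/mean of the RR~P fraction) is compared
at matched response fractions (10/30/50/70% of α). Pairing *independent*
draws instead mostly compares their saturation levels — the coefficient of
variation spans decades with the mean fraction — and washes out the regime
effect.

## Response times

The basal operating point for basal fraction b ∈ {0.2, 0.5, 0.8} is the
signal `k_s* = f(b·α)` — the signal producing that response level. (The
alternative literal reading, `k_s* = b·α`, mixes response units into the
signal and is not used.) The system starts at the exact steady state for
`k_s*`, the signal steps to `1.1·k_s*` (switch-on) or `0.9·k_s*`
(switch-off), and the stiff ODE (LSODA, rtol 1e-9) is integrated over a
doubling horizon until the derivative-norm criterion (max |dy/dt| <
1e-9 × largest total) holds and RR~P sits within the settling band. The
response time is the last entry into a band of 1% of the net response
change around the new steady state, refined by a root find on the dense
solution — making it insensitive to output granularity. Up and down steps
are computed independently; no symmetry is assumed.

## Variants

- **Bifunctional HK**: `HK + REC~P ⇌ C → HK + REC` (`k_5`, `k_5r`, `k_6`);
  the complex is a ninth species shared by the HK and REC conservation
  classes. With the complex at steady state (`C = k_5·HK·REC~P/(k_5r+k_6)`)
  the fixed point reduces to a one-dimensional root find in REC~P (bracketed
  between the REC-depletion and complex-vanishing points), giving a fast
  semi-analytic signal function; per-signal ODE integration is the generic
  fallback and the oracle in tests. Bifunctionality leaves α unchanged but
  raises the signal needed for any given response (sequestration +
  dephosphorylation), and lets topologies without REC hydrolysis reach
  sigmoidality.
- **Encounter complexes**: each transfer step runs through a reversible
  encounter complex with an irreversible transfer step (`on`, `off`, `cat`
  per channel; six extra species). The net steady-state rate per channel is
  `on·cat/(off+cat)`, which maps the model onto the simple one; with
  short-lived complexes the simple model's steady states are recovered
  quantitatively.
- **Turnover**: production of each unphosphorylated species at `δ·X_tot`
  and first-order removal of every form at δ. Steady-state totals stay at
  `X_tot`, and the fixed-point equations are exactly the simple model's
  with `k_h1+δ`, `k_h2+δ` and first-order losses δ on HK~P and Hpt~P — so
  the same elimination (and jet classification) applies. Sigmoidality no
  longer requires `k_h1 > 0` or `k_3r > 0` (a witness search with
  `k_h1 = k_3r = 0`, `k_4r > 0` succeeds).
- **HK / Hpt auto-dephosphorylation**: first-order `HK~P → HK` (`k_hk`) or
  `Hpt~P → Hpt` (`k_hpt`), entering the elimination as the corresponding
  loss terms. HK auto-dephosphorylation leaves the necessary conditions
  intact (no violating sigmoidal instance in large randomized searches);
  Hpt auto-dephosphorylation relaxes them — sigmoidality can arise with
  `k_h1 = k_3r = 0` when `k_4r > k_4` (witness search).

All variants with zero extra rates reproduce simple-model trajectories to
1e-9.

## Numerical choices

- ODE steady states: LSODA with a derivative-norm stopping criterion
  (max |dy/dt| < 1e-9 × largest total) over a doubling horizon; where
  1e-6-level agreement is asserted, the endpoint additionally seeds a
  Newton solve of the four phospho-balance equations (the integration
  criterion alone leaves ~1e-5 relative drift on stiff instances).
- Inversion of f and feasibility bisections: plain bisection with relative
  tolerances on the scale of `RR_tot`; f's divergence at α guarantees any
  signal is reachable.
- Jets are propagated through the same elimination code used for values,
  so derivative and value evaluations cannot drift apart.
- Degenerate inputs: zero required rates are rejected at parameter binding
  (they belong to a different topology); `f'(0) ≤ 0` raises an explicit
  indeterminate-curvature error rather than classifying.

## Problem sizes used in the shipped checks

Surveys use 1000 sets per topology (three seeds for seed-stability checks);
elimination/ODE equivalence uses 216 instances × 10 response levels;
classifier agreement 150 sets per topology; noise ordering 10 matched pairs
per topology at N = 10 with the N = 10 → 20 convergence check on an O(1)
instance; response-time comparisons 100 draws per regime per topology.

## Known limitations

- The sampling ranges are a stylized permissible regime; quantities that
  depend on the empirical distribution of kinetic constants (exact
  sigmoidal percentages, regime-resolved response-time contrasts) should
  not be read as predictions for any particular organism.
- The CTMC treatment requires equal layer totals (a single volume factor
  maps all totals to N molecules) and N ≳ 20 becomes expensive for exact
  solves.
- The symbolic closed forms of the steady-state polynomials and of the
  curvature expression are not reconstructed; all conclusions rest on the
  exact elimination and its exact derivatives.
- Passing the shipped synthetic-data checks demonstrates internal
  correctness of the solvers and classifiers, not agreement with any
  measured relay kinetics.
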