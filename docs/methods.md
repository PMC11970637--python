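# Methods

## Model class

hillnet integrates logic-based differential equations (LDEs): each species
has one state variable, its activity `y_i ∈ [0, ymax_i]`, interpreted as
fractional activation or expression. The dynamics are first-order
relaxation toward a logically computed target,

    dy_i/dt = ( ymax_i · F_i(y) − y_i ) / τ_i .

`F_i` is assembled from the reactions producing species `i`:

* a reaction's activity is `w · Π_r g(y_r)`, the continuous AND of one
  normalized Hill term per regulator, scaled by the reaction weight
  `w ∈ [0, 1]`; `g` is the activation `f` for activators and `1 − f` for
  inhibitors. A single `(n, EC50)` pair per reaction applies to all of its
  regulators, because the tabular format carries one `n` and one `EC50`
  column per reaction row.
* an input reaction (no regulators — an environmental stimulus) contributes
  its weight: the empty AND product is 1.
* reactions sharing a product are OR-combined by inclusion–exclusion,
  `a ⊕ b = a + b − ab`, folded over all contributors; the fold equals
  `1 − Π(1 − a_k)` exactly, which the tests use as an independent algebraic
  route. An empty fold is 0, so a species with no incoming reactions decays
  exponentially to zero (a convention — the bundled models have no such
  species).

The model is deterministic and continuous: unlike Boolean updating it
predicts graded, semi-quantitative crosstalk, while still requiring only
directionality (activates/inhibits) plus a handful of interpretable
parameters rather than measured kinetic constants.

### Assumptions

* Activities are normalized abstractions, not concentrations; mass
  conservation and stoichiometry are out of scope.
* Regulation is quasi-steady-state sigmoidal: all kinetic detail between two
  species collapses into `(w, n, EC50)`.
* AND regulators act independently (product form); OR contributions act like
  independent probabilities (inclusion–exclusion).

## The normalized Hill function

The activation nonlinearity is the unique scaled Hill curve through three
anchors — zero at zero input, half-maximal at `EC50`, maximal (1) at
saturating input 1:

    f(x) = B·xⁿ / (Kⁿ + xⁿ),  B = (EC50ⁿ − 1)/(2·EC50ⁿ − 1),  Kⁿ = B − 1.

Numerically the implementation evaluates the equivalent cleared form

    f(x) = (e − 1)·xⁿ / ((2e − 1)·xⁿ − e),   e = EC50ⁿ,

obtained by eliminating `B`. This form is exact at the anchors in floating
point and passes continuously through the singular locus `2·EC50ⁿ = 1`
(where `B` diverges), reducing there to the constrained-interpolation limit
`f(x) = xⁿ`. The shipped defaults (`n = 1.4`, `EC50 = 0.5`) are not
singular. Inputs above 1 (possible when some `ymax > 1`) are evaluated by
the same expression; the anchor guarantees are only claimed on `[0, 1]`,
and the bundled models never leave it. The unit tests check `f` against an
independent bisection fit of `B` to the anchor constraints and freeze
`f(0.25; 1.4, 0.5) = 0.215562963884608` computed by both routes.

## Parameters

| parameter | of | meaning | default | units |
|---|---|---|---|---|
| `tau` | species | relaxation time toward the driven target | 1 | time (arbitrary) |
| `yinit` | species | activity at session start | 0 | activity |
| `ymax` | species | maximal attainable activity; 0 encodes a knockout | 1 | activity |
| `weight` | reaction | strength/on-off of the influence | **none** | – |
| `n` | reaction | Hill cooperativity (> 0) | 1.4 | – |
| `EC50` | reaction | half-activation input, in (0, 1) | 0.5 | activity |

`weight` deliberately has no default: it is the on/off switch for stimuli,
so a blank weight cell in a model table is a validation error rather than a
silent assumption. `ymax = 0` is legal (knockout). `yinit > ymax` is legal
but flagged with a warning diagnostic — the knockout workflow creates it
transiently (e.g. a repressed gene starting at 1 when its ceiling is 0) and
the dynamics simply decay toward the reachable range.

## Simulation protocol semantics

A `SimulationSession` emulates an interactive simulate–perturb–simulate
workflow: each segment applies parameter overrides (which persist until
changed or reset), integrates from the current state for the segment's
duration, and appends to the cumulative trajectory. "Reset" restores
pristine parameters and/or the initial state; a `yinit` override takes
effect at session start or reset, never retroactively mid-run. Default
segment duration is 10 time units.

Integration uses scipy's BDF (a stiff-capable implicit multistep method of
the same family as MATLAB's ode15s) with `rtol = 1e-6`, `atol = 1e-9`. The
contract is tolerance-based, not method-based; the continuation property
(one segment of length 2d equals two of length d to 1e-5) is tested on the
bundled models. Output is sampled on a fixed grid of 201 evenly spaced
points per segment, independent of internal solver steps, so trajectories
are deterministic and plot-ready; consecutive segments share their boundary
point, which is stored once.

A species knocked out with `ymax = 0` and `yinit = 0` has the right-hand
side `−y/τ` with `y(0) = 0`, and BDF keeps it at exactly 0.0 at every
output time — no clamping is applied anywhere.

`steady_state` integrates in 50-unit chunks until `max|dy/dt| < 1e-9`
(horizon 1e5, after which non-convergence is reported as an error, since
oscillatory models exist in principle). It is cross-checked against an
integration-free oracle: damped fixed-point iteration
`y ← (1−α)·y + α·ymax·F(y)` (α = 0.5, tolerance 1e-12) on the same map.
Both routes start from `yinit`, so in multistable models (the bundled
five-species stimulation model latches via its positive feedback loop) they
track the same basin; agreement to 1e-4 is asserted on both bundled models
and on 50 seeded random models of 2–8 species.

## Model tables

The workbook dialect holds `species` (`ID, name, Yinit, Ymax, tau`) and
`reactions` (`module, ID, Rule, Weight, n, EC50`) sheets; sheet and column
names match case-insensitively with whitespace stripped, unknown columns are
preserved as pass-through metadata, and blank cells take the defaults above.
The CSV dialect is a directory with `species.csv`/`reactions.csv` and the
same headers, so models remain usable without spreadsheet tooling. Rule
cells starting with `=` are written with a leading apostrophe (the
spreadsheet text-guard, so the cell is not parsed as a formula) and the
apostrophe is stripped on load. The rule grammar is
`[!]R1 [& [!]R2 ...] => P`; `|` is rejected because OR is expressed
structurally by multiple reactions sharing a product. The `module` column is
a grouping label only. Edge export emits one SIF line per
(reaction, regulator) pair plus an `INPUT_<product>` pseudo-source line per
input reaction, in model order, with interaction vocabulary
`{activates, inhibits, input}`.

## Random-model generator

`random_model(n_species, edge_density, seed)` supports the property suites:
per species an input reaction with probability `edge_density`, per ordered
species pair a one-regulator reaction with the same probability
(activator with probability 0.8), `tau ~ U[0.1, 10]`, `ec50 ~ U[0.2, 0.8]`,
`n ~ U[1, 4]`, `weight ∈ {0, 1}`, `yinit ~ U[0, 1]`, `ymax = 1`. The ranges
are this package's choice of a realistic envelope around the defaults; the
generator is seeded and reproducible. It emulates the structural shape of
curated signaling models (sparse, mostly activating, switch-like weights)
but not their biological wiring — passing property tests demonstrates
numerical correctness (forward invariance of `[0, ymax]`, oracle agreement,
continuation), not predictive accuracy on real networks.

## Problem sizes

The test and acceptance workloads use the two bundled five-species models
and random models of up to 8 species (50 seeds for the property suites);
the full suite runs in well under a minute on one CPU. The engine itself is
size-agnostic — the right-hand side is assembled per reaction — but no
large-network performance work (vectorized gate evaluation, sparse
Jacobians) has been done.

## Known limitations

* Qualitative/semi-quantitative predictions only; weights and Hill
  parameters are not fitted to data (no parameter estimation or uncertainty
  quantification).
* No discrete Boolean mode, stochastic dynamics, delays, or event
  detection.
* In the stimulation scenario, the last species of the A → C → E cascade
  reaches activity 0.99865 (not 1 − 1e-3) ten time units after stimulus
  onset with all-default parameters: "saturates to 1" holds at two-decimal
  resolution, and the scenario report asserts it at that resolution.
* Multistability is real in these models (positive feedback latches); both
  steady-state routes are basin-dependent by design, starting from `yinit`.
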