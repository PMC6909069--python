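# Methods

## Model

The simulation is an iterated two-player Prisoner's Dilemma played on a
square lattice, extended with three survival rules: payoffs accumulate as
wealth, every interaction costs each participant a fixed consumption amount
(the turn cost), and a player whose wealth falls to or below zero dies and
is permanently removed.  The model is deliberately *non-evolving*: players
never change strategy, the dead are not replaced, and there are no external
shocks.  What is studied is therefore not the evolution of cooperation but
the fate — population and wealth — of each (initial class × strategy)
category under survival pressure.

Gross payoffs are a PD matrix (T, R, P, S) = (2.2, 1.1, 1.0, 0) at
baseline.  A matrix is *conservative* when T + S = 2R; the flag is derived,
never stored, so non-conservative variants such as (2.0, 1.1, 1.0, 0) are
handled uniformly.  Settlement is exact real arithmetic: net = gross −
turn_cost, computed net-first so that cost-neutral configurations (e.g. an
all-defect society at cost P) leave wealth bit-for-bit unchanged.

## Strategies

All six strategies share a tit-for-tat base: cooperate on first encounter,
otherwise echo the opponent's last observed move, with probability
`forgiveness` (default 0.10) of cooperating when the base rule would
retaliate.  Memory is memory-one and per neighbour; a forgiving move does
not erase the remembered defection.  The five conditioned strategies add
one wealth trigger each that forces defection: Subsist at own wealth ≤ 4,
Middle at own wealth ≤ 8, Exploit when own wealth ≥ 2× the opponent's,
Thief when the opponent's wealth ≥ 2× one's own, AlwaysDefect always.
Threshold comparisons are inclusive (≤, ≥); ratio triggers use current —
not initial — wealth of both parties, i.e. wealth is mutually visible.

## Round structure and micro-semantics

A round plays every edge between live players exactly once, in sorted edge
order.  Both players decide simultaneously from the current state, both
record the opponent's move, and both settle.  Three points the rules leave
genuinely open are implemented as explicit policy switches, with defaults
chosen as follows:

* **Death check** (`death_check`): per interaction (default) or end of
  round.  Immediate removal is the only order under which survivors'
  "fewer turns per round" is well defined.
* **Settlement** (`settlement`): sequential in-place (default) or
  simultaneous from a round-start wealth snapshot.  Sequential settlement
  makes runs exactly reproducible from the seed.
* **Reconnection** (`reconnect`): when a player dies its live former
  neighbours are joined in disjoint consecutive pairs of the sorted
  neighbour list ("pairing", default), so each survivor regains at most
  the one link it lost and degrees stay lattice-like (≤ 4).  A "clique"
  policy (all pairs) and "none" are also available.  Pairing is the
  default because the clique rule has a structural pathology: whenever
  die-off is substantial, survivor degrees grow without bound (mean degree
  above 50 within 30 rounds in a 3-strategy baseline run) and the number
  of interactions per round *rises* as the population falls, so
  consumption accelerates and the society collapses.  That contradicts the
  model's own premise that players have at most four turns per round and
  that survivors of a death see fewer, not more, interactions.

Edges created by mid-round reconnection enter play from the next round.
The random stream is consumed in a fixed order — class assignment,
strategy assignment, then per-interaction forgiveness draws — so a
configuration and seed determine the trajectory bit for bit; with
forgiveness 0 the trajectory is a deterministic function of the initial
assignment.  Replicate r of a Monte Carlo run is seeded from
`SeedSequence([base_seed, r])`.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| turn_cost | 1.07 | tokens/interaction | consumption; the standard-of-living dial |
| forgiveness | 0.10 | probability | chance a retaliation becomes cooperation |
| rows × cols | 20 × 20 | — | bordered lattice, 19 % border nodes |
| rounds | 50 | — | ≈ 200 interactions for an interior player |
| density_poor | 0.5 | probability | chance a node starts poor |
| wealth_poor / wealth_rich | 4 / 10 | tokens | poor start ≈ one round from death |
| subsist / middle threshold | 4 / 8 | tokens | one- and two-round survival margins |
| wealth_ratio_trigger | 2 | — | Exploit/Thief trigger ratio |

The defaults are the study conditions: the poor start close enough to the
survival threshold that strategy choice matters, while 1.07 sits near the
wealth equilibrium of the mixed society, so populations neither run away
rich nor collapse trivially.

## Equilibrium search

The *wealth equilibrium* turn cost makes a target class's mean total
wealth after the run equal its initial total.  `find_equilibrium_turn_cost`
bisects the turn cost over [0.5, 1.6] against the Monte Carlo mean wealth
change, reusing the same replicate seeds at every evaluation (common
random numbers), which makes the objective effectively monotone in the
cost and bisection sound despite sampling noise.  The default residual
tolerance is 0.5 % of the class's initial wealth, with a bracket-width
floor of 0.002.  Two closed forms anchor the machinery: an all-TitTat
society (no defection ever) equilibrates exactly at R, and an all-defect
society at P.

## Problem sizes

Headline estimates use 100 replicates of the 20×20 / 50-round
configuration, which puts Monte Carlo standard errors on survival
fractions below one percentage point per category.  The large-lattice
scaling comparison in the test suite uses a 40×40 toroidal lattice at 20
replicates, and distribution-shape checks use 300 replicates of the
3-strategy mix — sizes chosen so the whole suite runs in a few minutes
while keeping each check's statistical resolution well inside the
tolerance it asserts.

## Synthetic reconciliation fixture

The reconciliation pipeline (normalized temptation → curve-interpolated
cooperator density → Pearson correlation and displacement constant) is
designed for externally supplied curve and country tables; the package
embeds none.  `generate_curve_fixture` produces a strictly decreasing
synthetic density curve over b ∈ [1, 2] and a country table whose observed
fractions are the curve's own predictions plus a known displacement and
optional Gaussian noise.  A noise-free run must return r = 1.0 and recover
the displacement exactly, which validates the pipeline's plumbing — it
says nothing about how well any real network's temptation curve predicts
real behaviour.  The stake→temptation mapping b = 1 + stake/(daily wage)
is the simplest form with the correct no-temptation limit (b = 1 at zero
stake) and is injected as a replaceable function, since empirical uses may
require a different calibration.  Out-of-range temptations are clamped to
the curve's terminal densities, never extrapolated.

## Numerical choices

Token amounts are double-precision reals with no rounding anywhere in
settlement.  The per-round conservation identity (Σ wealth change =
Σ gross − 2·cost·interactions) is asserted to 1e-9 per round.  Histogram
binning uses width-1 bins on [0, 50] with out-of-range wealth clipped into
the terminal bins, so counts always sum to the live population.  Ties in
the strategy draw are impossible (categorical draw); ties in edge order
are impossible (sorted unique pairs).  Degenerate inputs — 1×1 lattices,
zero rounds, empty strategy mixes, non-PD matrices — are either
well-defined (the first two) or rejected with named violations.

## Known limitations

* Quantitative survival rates in this model family are sensitive to
  micro-semantics that published descriptions underdetermine (decision
  order within an interaction, memory initialisation, reconnection
  topology).  Our implementation fixes each such point explicitly and
  exposes the main ones as policy switches; under the defaults the
  qualitative results — strategy ordering (Middle best for both classes,
  TitTat worst for the rich, poor TitTat/Exploit worst overall), the
  ≈1.07–1.08 mixed-society equilibrium, the closed-form equilibria, and
  heavy die-off at raised cooperation benefit — are robust, but
  category-level survival percentages can differ substantially from other
  implementations of the same rules.  All reported figures are computed,
  never calibrated to match external values.
* The borderless scaling comparison is run at moderate lattice sizes; the
  engine accepts arbitrarily large lattices but is pure Python, at roughly
  0.1 s per 20×20×50-round simulation.
* Uniform-wealth cooperating societies stay uniform only because the model
  has no exogenous shocks; none of the simulations here say anything about
  robustness to crop failure, migration, or conflict.
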