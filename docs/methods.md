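# Methods

## The patch-switching game

*C. elegans* foraging on patchy bacterial lawns faces a sequence of
decisions: remain on the current patch, switch (follow pheromone cues to
another occupied patch), or disperse (avoid pheromone cues and search for
unoccupied habitat). The core model is a symmetric two-patch game. `n1`
worms start in patch 1 and `n2` in patch 2, with `n1 >= n2 >= 1` so patch 1
is the overcrowded one; each patch holds `A_E` units of food. A worm cannot
tell which patch it is in (it has no reliable information about the other
patch's density), so a single switching probability `p` applies to every
worm. A switcher relocates by following pheromone and may end up back where
it started, landing in either patch with probability 1/2, and pays a cost
`c` (in the same food units as `A_E`: energy and risk of travel expressed as
foregone food).

Expected occupancy after the switching round is

    m_i(p) = n_i (1 - p) + (n1 + n2) p / 2,

food is shared evenly, so per-capita intake in patch i is `G_i = A_E / m_i`,
and the strategy payoffs are

    H_Remain(p) = sum_i (n_i / N) A_E / m_i(p)
    H_Switch(p) = sum_i (1/2)    A_E / m_i(p) - c,        N = n1 + n2.

The weights differ because a remaining worm sits in patch i with its prior
probability `n_i / N`, while a switcher lands with probability 1/2. The gap
`H_Switch - H_Remain` is strictly decreasing in `p` for `n1 > n2`: switching
is profitable while the overcrowded patch is likelier than the landing
lottery, and the advantage erodes as switching equalizes occupancies.

**Equilibrium.** The evolutionarily stable switching probability `p*` is
the mixed strategy at which no deviation pays. With `c = 0` and unequal
patches the gap stays non-negative up to `p = 1`, so everyone switches and
the distribution equalizes (the ideal-free-distribution outcome). With
`0 < c < gap(0)` there is a unique interior root; it is found by bisection
(`scipy.optimize.bisect`, absolute tolerance 1e-10, 200-iteration cap —
global convergence is guaranteed by monotonicity). Costs at or above
`gap(0)` give `p* = 0`. The degenerate case `n1 = n2, c = 0` makes the gap
identically zero; every `p` is an equilibrium and the solver returns 0
flagged `neutral` so the output stays deterministic. At the `p = 1`
boundary the payoffs obey the closed identity `gap(1) = -c` exactly; the
solver uses that identity rather than the numerically evaluated sum, whose
~1e-16 residue would otherwise misclassify the costless boundary.

Worm counts are accepted as positive reals, not only integers: the
equations are continuous in `n_i`, and the equilibrium surface
`p*(c, n1/N)` varies the initial fraction continuously at fixed `N`.
Inputs with an empty patch (`n_i < 1`) are rejected — the model assumes two
occupied patches.

**Population payoff.** Averaging over strategies gives
`H_all = 2 A_E / N - p c`: the total food is fixed, so switching is neutral
for the population when costless and strictly deleterious when costly. The
equilibrium is therefore driven purely by intraspecific competition.

## The stochastic simulator

`patchforage.sim` replays the same episode with discrete worms on `K >= 2`
patches of arbitrary sizes: one switching round (each switcher lands
uniformly over the K occupied patches, generalizing the 1/2 rule), even
sharing of each patch's food among its occupants, then a dispersal phase.
Dispersal is withheld until the occupied patches are depleted — worms do
not abandon food that is still worth eating, the patch-residence logic of
the marginal value theorem — after which each disperser independently finds
the unoccupied patch with probability `s` and successful finders share
`A_U` evenly. `dispersal_advantage` exposes the underlying comparison for a
lone worm: `s * A_U` against the stayer's share `f * sum(A_i) / N` of the
remaining food fraction `f`; the advantage rises monotonically as `f -> 0`
and is positive only near depletion.

A patch that ends the switching round with zero occupants is not written
off: once worms deplete their own patch they keep foraging among occupied
patches, so stranded food is eventually found, and the simulator books it
as an even N-way share (the mean-field limit of that search). This keeps
total intake equal to total food and makes the population mean intake match
`H_all` exactly in expectation; treating stranded food as lost instead
would depress mean intake by about `A_E P(empty) / N` (~0.003 food units at
N=10, p=0.5), a visible artifact of small populations that the model's
continuum narrative does not intend.

Randomness: every entry point takes an integer seed; replicate `r` draws
from `numpy` sub-stream `(seed, r)`. Identical seeds give bit-identical
results, and sweeps sharing a seed (a mutant grid in an invasion study)
share their noise replicate by replicate, so strategy comparisons are
paired.

**Invasion tests and finite-population effects.** `invasion_payoff` makes
one focal worm (origin drawn with the occupancy prior `n_i / N`) play a
mutant switching probability against residents playing `p`. Two caveats,
both verified against an exact enumeration oracle in the test suite:

* At the resident's own strategy, the focal's expected intake equals
  `H_Remain(p*) = H_all(p*)` exactly.
* At small N the continuum `p*` is **not** the finite-population optimum.
  A real worm is not a rare mutant: at N=10 its body adds a whole
  competitor to whichever patch it joins, so the exact invasion payoff
  declines linearly in the mutant's switching probability (slope about
  -0.024 at the reference parameters 9/1, `A_E=1`, `c=0.1`), and a
  non-switching mutant beats the `p*`-playing resident by ~0.009 food
  units. This is a property of the model at N=10, not simulator noise.
  Scaling worms and food together (e.g. 180/20 worms, `A_i = 20`) leaves
  per-worm payoffs and `p*` unchanged while shrinking the self-competition
  term, and the mean-field equilibrium then resists all mutants within
  Monte-Carlo resolution; the suite tests exactly that. An acceptance-style
  check that demands uninvadability at N=10 itself will correctly fail,
  and is left failing rather than masked.

## Assay statistics

The chemotaxis index CI = (Np - Nc) / (Np + Nc) compares worm counts within
the scoring radius of a pheromone spot and a control-solvent spot; +1 is
unanimous attraction, -1 unanimous avoidance. Zero choosers make the index
undefined — "no choosers" is not "no preference" — so scalar calls raise and
tabular routines propagate a missing value excluded from means.

Per-scenario summaries aggregate in two stages, mirroring the experimental
design: within each independent experiment the ~10 replicate assays are
pooled (Np and Nc summed) into one per-experiment CI, then the mean and SEM
(sample SD over sqrt(n), n = number of experiments) are taken across
experiments. Pooling is the default because replicate assays hold only ~50
worms and a ratio of sums is less biased than a mean of small-count ratios;
`aggregation="mean"` provides the alternative for sensitivity checks. A
single experiment yields SEM 0 with an explicit degenerate flag.

Hourly CI in the choice-after-food assay uses only the worms newly arrived
at a spot during that hour, so each hour reflects the preference of the
cohort that left the patch around then.

## Synthetic data

The generators produce count tables with the statistical structure the
analysis assumes, for pipeline testing without any download.

*Conditioning assays*: each worm is a non-chooser with probability 0.2
(source data do not report the rate; a fifth of worms failing to commit
within the hour is a plausible placeholder) or else picks the pheromone
spot with a scenario probability `q`, so pooled CI converges to `2q - 1`.
Defaults: 4 independent experiments x 10 replicates x 50 worms, the
replication reported for the conditioning experiments.

*Choice-after-food time courses*: 50 worms on a patch of 120 food units,
consuming 1 unit per worm-hour; each hour a worm leaves with hazard
`0.15 * (1 + 5 * (1 - food_fraction))`, capped at 1, evaluated on the food
fraction at the start of the hour, and the remaining worms then eat. The
hazard form (baseline times a depletion-scaled boost) is a stand-in — the
source literature is qualitative about the mechanism — with defaults chosen
once so that leaving accelerates as the patch runs down and >85% of worms
are gone by hour 5. Leavers commit immediately to a spot (`q_early = 0.7`
through hour 3, `q_late = 0.3` after), final on arrival as under azide
immobilization; the hourly CI therefore flips sign at the switch hour, the
preference-inversion signature. Two experiments of 10 replicates by
default.

What the generators do **not** emulate: plate geometry and diffusion
gradients, between-assay heterogeneity in worm counts and non-chooser
rates, learning kinetics (the inversion is imposed as a step change in `q`,
not learned), and worms re-emerging from a spot. Tests passing on this
synthetic data validate the statistical pipeline and the model's
qualitative signatures, not the biology of any particular dataset.

## Numerical and design choices

* Problem sizes: Monte-Carlo checks use 1e4 episodes (mean-field agreement,
  invasion grids) or 100 seeded generator runs (sign signatures); these
  give standard errors comfortably below the effects tested.
* Equilibrium surface grids clamp `n2` to 1 when floating-point rounding of
  `(1 - f) N` lands within 1e-9 below it; fractions implying `n2 < 1` are
  rejected.
* CSV IO validates schemas strictly (exact column sets, non-negative
  integer counts, spot counts bounded by worms placed) and reports the
  offending row and column; unknown config keys are rejected rather than
  ignored.
* All dataclass configs validate on construction; probabilities are checked
  to [0, 1] at every public entry point.

## Known limitations

* The dispersal phase is a single terminal round with a scalar success
  probability; continuous-time patch departure and spatial search are out
  of scope.
* Landing probabilities are uniform over patches. If pheromone output
  scales with occupancy, landing odds should tilt toward crowded patches;
  the episode engine accepts per-worm switch probabilities, but
  occupancy-weighted landing is not implemented.
* The finite-population deviation from the continuum equilibrium described
  above means small-N simulations should not be used to localize `p*`
  to better than O(1/N).
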