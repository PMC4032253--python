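# Methods

## Model

### Potential synapses

A network between an address population of m neurons and a content
population of n neurons is described at the resolution of *potential
synapses*: locations where a synapse could grow. Each location is in state
`P` (not realized), `0` (realized, silent), or `1` (realized,
consolidated). A binary consolidation signal `Z ∈ {0,1}^{m×n}` tags the
pairs requested by the memories currently rehearsed; here `Z` is the
Willshaw matrix of the active memory block, i.e. `Z_ij = 1` iff some memory
in the block activates both neuron i and neuron j.

Per time step, transitions apply in a fixed order:

1. **consolidation** — every silent synapse at a requested pair moves to
   state 1 with probability `p_cons`;
2. **deconsolidation** — every consolidated synapse at an *unrequested*
   pair moves to state 0 with probability `p_dec`; requested consolidated
   synapses are retained (immediately reconsolidated);
3. **elimination** — every silent synapse is removed (state `P`) with
   probability `p_elim`;
4. **generation** — under *count-matched homeostasis*, exactly as many new
   silent synapses as were just eliminated appear at uniformly chosen free
   potential locations, blind to `Z` (no plausible mechanism can deliver a
   pair-specific signal to a nonexistent synapse); without homeostasis each
   free location realizes with probability `p_gen`.

Counting elimination before generation makes the homeostatic match exact:
in the single-synapse model the anatomical connectivity `c_a` is constant
to the synapse, in the multi-synapse model the synapse budget `N_syn` is.
Newly generated synapses always enter state 0, even at requested locations,
and can consolidate only at the next rehearsal step; this keeps structural
and weight transitions separate and is observable in the trajectories (the
theory below depends on it). Consolidated synapses cannot be eliminated
without first deconsolidating — there is no direct `1 → P` transition.

Two variants: **single** (at most one synapse per neuron pair; states are
pair states) and **multi** (a fixed budget of `N_syn` synapses, each
allocated to any potential pair independently, so pairs can hold several; a
pair counts as connected/consolidated if it holds at least one). Both give
statistically indistinguishable effectual-connectivity trajectories for
short replay; under very long replay the multi model piles synapses onto
requested pairs.

### Connectivity measures

- anatomical `c_a`: density of pairs with ≥ 1 actual synapse;
- potential `c_p`: density of pairs with ≥ 1 potential location;
- effectual `c_e`: fraction of requested pairs (`Z = 1`) holding ≥ 1
  consolidated synapse;
- consolidation load `P1`: density of ones in `Z`;
- filling fraction `f = c_a / c_p`.

### Macroscopic dynamics of c_e

For a large single-synapse network with constant `c_a`, constant signal
presented every step, `p_cons = 1`, and count-matched homeostasis, write
`G(t)` for the probability that a requested potential location is still
unconsolidated. Then

    c_e(0) = c_a · f1c                      (f1c = initially consolidated fraction,
                                             at locations independent of Z)
    c_e(1) = c_a                            (first rehearsal consolidates every
                                             realized requested synapse)
    c_e(t) = c_p · (1 − G(t)),
    G(t)   = (1 − c_a/c_p) · Π_{s=1}^{t−1} (1 − q(s)),
    q(s)   = p_elim · s0(s) / (c_p − c_a)

where the migratable silent fraction is

    s0(s) = c_a − c_a·f1c·(P1 + (1 − P1)(1 − p_dec)^s) − P1·(c_e(s) − c_a·f1c)

(all real synapses, minus surviving initially consolidated ones, minus
those newly consolidated at requested locations), clamped at zero. When
`P1·c_p` exceeds the available budget the pool runs dry and `c_e` converges
to a limit near `c_a/P1` instead of `c_p` — large consolidation loads slow
and ultimately cap consolidation. For small load and `p_dec ≈ 0` the
product collapses to the exponential form

    c_e(t) ≈ c_p − (c_p − c_a) · exp(−p_elim · c_a(1 − f1c)/(c_p − c_a) · (t − 1)).

The recurrence is an expected-value description; the acceptance suite
verifies that single microscopic runs at m = n = 1000 stay inside the
4·sqrt(c_e(1−c_e)/#requested) binomial band at every one of 200 steps, for
consolidation loads 0.01–0.5, initial consolidation 0–0.9, and anatomical
connectivities 0.08–0.12.

### Storage and retrieval

Hebbian clipped (Willshaw) storage: `W_ij = 1` iff the pair is connected
and some stored memory activates both neurons. Retrieval propagates a query
through `W` and thresholds the dendritic potentials; strategies are
k-winners-take-all (exactly l winners, ties to the lowest index),
per-neuron thresholds equal to the number of *connected* active inputs
(never misses when add noise is zero), or a fixed scalar. Iterative
retrieval adds auto-associative cleanup steps through a prewired content
network with silenced self-connections; it makes per-memory outcomes nearly
all-or-none.

### Capacity theory

Asymptotic path (connected-count thresholds, misses impossible):
memory load `p1 = 1 − (1 − kl/mn)^M`; low-unit false-positive probability
`p01 = (1 − P + P·p1)^{λk}` (equal to its binomial sum; the independence it
assumes holds asymptotically for small assemblies — at m = n = 500 its
finite-size bias is +16% for k = 10 but <3% for k = 6, and the exact
inclusion–exclusion probability is implemented alongside for validation);
maximal load `p1max` solves `(n−l)/l · p01 = ε` (bisection to 1e−12, closed
form `(εl/(n−l))^{1/λk}` cross-checked at P = 1); pattern capacity
`M_ε = ⌊ln(1 − p1max)/ln(1 − kl/mn)⌋` with the exact logarithm ratio rather
than its asymptotic simplification; weight capacity
`C = M_ε · n · T(l/n; p01, p10) / (m·n·P)` bits per anatomical synapse with
`T` the binary-channel transinformation; total capacity divides instead by
the consolidated synapses `m·n·c_e·p1max`. `C ≤ ln 2` for noiseless
complete queries; `C_total` grows without bound in n for fixed sparse k —
the quantitative payoff of structural plasticity.

Finite-network path: exact low/high-unit potential moments (pairwise
weight covariance for inputs sharing a content unit is computed exactly
from hypergeometric assembly-overlap probabilities; dilution enters by the
law of total variance over the binomial connected-input count), a
continuity-corrected Gaussian scan for the optimal integer threshold, and a
monotone binary search for the largest admissible M. An exact potential
pmf (inclusion–exclusion, binomial dilution mixture) serves as the
small-instance oracle.

## Experiment protocols and default parameters

All protocols share: populations of n = 1000, assemblies of k = l = 50,
queries with completeness λ = 0.9 and add noise κ = 0.1, `p_cons = 1`,
`p_dec = 0`, count-matched homeostasis, and retrieval evaluated through 3
auto-associative cleanup iterations against a prewired static content
network storing all blocks' patterns. Block counts, memories per block, and
elimination rates per protocol: 25 blocks × 4 at `p_elim = 1` (structural
sequential learning), 25 × 12 at `p_elim = 0` (frozen-structure baseline),
6 × 4 at `p_elim = 1` (lesion), 1 × 20 at `p_elim = 0.01` (spacing).
Consolidation-dynamics runs use the single-synapse model with k = 10,
`c_a = 0.1`, `c_p = 1`, `p_elim = 0.1`, one block rehearsed 200 steps.

The connectivity levels are package choices, set so each protocol sits at
its intended operating point:

- **structural sequential learning**: `c_a = 0.04`, `c_p = 1`, cleanup
  connectivity 0.45. The migratable pool (`c_a·m·n` synapses) must be
  exhausted within 25 blocks for late blocks to fail while the cleanup
  basin still rescues the early, well-consolidated blocks; a denser cleanup
  (≥ 0.5) rescues even unconsolidated blocks, a sparser one (≤ 0.3) injects
  enough threshold noise to break the early blocks.
- **frozen-structure baseline**: `c_a = c_p = 0.1` (single-synapse model so
  the frozen connectivity is exact), cleanup 1.0. 300 memories overload
  this network several-fold: every block, including the first, ends above
  output noise 0.5 — catastrophic forgetting. Early in the run the same
  network retrieves perfectly.
- **lesion**: `f1c = 0.8` (an adult network whose synapses are mostly
  claimed by old memories, leaving a small migratable pool that six blocks
  deplete appreciably), 10 rehearsal steps per block, cleanup 0.3. The 50%
  address lesion then lands retrieval on the failure boundary so the c_e
  recency gradient maps onto an output-noise gradient.
- **spacing**: `f1c = 0.7`, `p_elim = 0.01` (structural turnover ~100× slower
  than consolidation), four 5-step windows separated by 45 idle steps vs one
  20-step window on a seed-matched network, cleanup 0.45. Idle gaps let
  turnover plant fresh silent synapses on requested pairs; each brief window
  harvests them. With `p_cons` lowered to the turnover scale the effect
  vanishes, as the mechanism predicts.

The retention criterion "a block is retained if its mean output noise
≤ 0.2" is a package convention used for summaries; the underlying curves
are continuous.

## What the synthetic data does and does not emulate

Memory patterns are uniform random size-k subsets, independent across
memories — the exchangeable-assembly idealisation behind every formula
above. Real cortical representations are correlated, unit usage is skewed,
and consolidation signals are noisy rather than binary; passing tests
therefore validate the model's internal consistency and its stated
asymptotics, not fits to biological recordings. The simulation time step is
calibrated only by the mean lifetime `1/p_elim` of an unrequested silent
synapse (days, for unstable spines), so absolute times are in model steps.

## Numerical choices and limitations

- All randomness flows through explicitly seeded numpy Generators; one
  stream drives structure/patterns, one plasticity, one evaluation, so
  adding evaluation never perturbs a trajectory. Seed-matched runs are
  byte-identical.
- kwta ties break toward the lowest neuron index; iterative retrieval zeroes
  each unit's own recurrent input.
- Degenerate cases: an all-zero consolidation signal has undefined c_e
  (error); count-matched generation with no free potential location is an
  error; `λk` rounding to zero queries is an error. Fractional counts λk,
  κk round to nearest.
- The Gaussian threshold analysis is accurate when the optimal threshold
  sits within ~2 standard deviations of the potential means (tolerated
  output noise ≳ 0.1 for n = 1000, k = 30). At much smaller noise levels the
  skewed upper tail of the Willshaw–Palm distribution dominates and the
  Gaussian path overestimates capacity (about 2× at ε = 0.01, n = 1000,
  k = 30); the exact pmf is the remedy at small sizes. Validation against
  simulation is therefore run at ε = 0.2, matching the retention level.
- The macroscopic recurrence assumes a single synapse per pair; no
  closed-form theory is provided for the multi-synapse variant (simulation
  only).
- Pattern capacities at n = 10⁶ are evaluated analytically; no simulation at
  that size is attempted.
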