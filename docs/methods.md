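# Methods

This note records the models, conventions and parameter choices behind
`cryptlineage`, in enough detail to reproduce or audit any number the
package computes.

## Proliferative-state classification

A tracked cell is classified from its lineage record alone:

| rule (first match wins) | state |
|---|---|
| seen to die (extrusion flag) | dead |
| division observed (two daughters) | proliferating |
| followed ≥ `min_nondividing_obs` = 30 hr without dividing | non-proliferating |
| last axis position > `villus_cutoff` = 60 µm | non-proliferating |
| otherwise | undetermined |

The 30-hr rule rests on the cycle-time distribution: under the default
skew-normal fit, P(cycle > 30 hr) ≈ 7×10⁻⁷, so a cell watched that long
without dividing has effectively ceased. The 60-µm rule reflects that
divisions are confined to the proliferative region near the crypt base.
Cells born less than `end_exclusion` = 15 hr before the recording ends
are flagged and excluded from pair statistics — they rarely live long
enough to classify, and keeping them would bias pair tallies toward
fast-dividing outcomes. Lost cells that match neither
non-proliferation rule stay undetermined; we do not guess, although an
optional classifier mode (`assume_unclassified_nonproliferating`) exists
for the balance check in which every unclassified cell is presumed
arrested.

## Pair statistics and the (α, φ) estimator

Sisters share a parent; cousins share a grandparent but not a parent (any
resolvable cousin pair counts, all four grandchildren need not be
tracked). Each unordered pair enters once. Death dominates: a pair with
a dead member goes to a death category, never to the
proliferate/stop tallies; pairs with an undetermined or excluded member
are set aside. Category fractions are reported under two normalizations
(with or without death pairs in the denominator) and the caller picks one
explicitly.

With division modes drawn as p_pp = (φ+α)/2, p_nn = (φ−α)/2,
p_asym = 1−φ, the inversion is linear in the observed fractions:
φ̂ = f_pp + f_nn, α̂ = f_pp − f_nn, with multinomial standard errors
se(α̂) = √((φ − α²)/n) and se(φ̂) = √(φ(1−φ)/n). The sister cycle-time
correlation is a Pearson coefficient with each pair entered in both
orders, making it invariant to pair-member labels; it uses only pairs in
which both sisters divided.

## Crypt geometry

The crypt axis is an annotated set of 3–6 control points per time point,
interpolated with a natural cubic spline (a straight segment for two
points), densely resampled and re-parameterized by arc length in 0.5-µm
steps. A cell at x projects to r* = argmin_r |s(r) − x| (1-µm grid scan
refined by bounded minimization; ties break toward smaller r; the
vectorized path uses a parabolic sub-grid step, accurate to ~0.01 µm).
Positions are reported as p = r* − min_i r*_i, so the bottom-most cell of
each frame sits at p = 0, and the angle θ = acos(u·v/|v|) against the
viewing direction u = (0, 0, −1). θ is an arccos and carries no sign:
mirror-image positions coincide, which is the convention used throughout.

Neighbour graphs link each cell to its five closest cells within 15 µm
(nuclei are ~10 µm with about five neighbours); the directed relation is
symmetrized by union. The Paneth link distance δ is the edge count to
the nearest Paneth cell minus one — a direct neighbour has δ = 0 — and a
cell's lifetime δ is the mode of its per-frame values, ties toward the
smaller δ. Paneth cells themselves carry δ = 0 for bookkeeping; they
never divide and never enter mother-division statistics.

## Growth fits and fluctuation measures

The growth model is the Uniform division scheme: dN/dt = (α/T)N and
births at rate N/T, giving N(t) = N₀e^{αt/T} and
U(t) = U₀ + N₀·(t/T)·φ₁(αt/T) for the cumulative number of cells born,
with φ₁(y) = (e^y − 1)/y evaluated by `expm1` (continuous at α = 0, where
U grows linearly). The fit takes N₀ and U₀ from the first time point and
minimizes the unweighted joint sum of squares over the single parameter
α ∈ [−1, 1].

Fluctuation statistics are dwell-weighted: the count is piecewise
constant between observations, mean = ΣNᵢΔtᵢ/ΣΔtᵢ and
σ² = ΣNᵢ²Δtᵢ/ΣΔtᵢ − mean², and a series is called sub-Poissonian when
σ < √mean. The same moments (accumulated relative to the initial counts
to avoid cancellation) summarize the simulators, including the
niche/differentiation covariance decomposition
σ² = σ²_n + σ²_d + 2cov(N_n, N_d).

## Bootstrap procedures

The independence null draws, per iteration, n sister pairs whose members
are independently proliferative with probability p and records the
concordant fraction Φ; its analytic mean is p² + (1−p)². Tail p-values
are reported as the upper bound 1/n_iter when no iteration reaches the
observed value — never as zero. Clone-size uncertainties resample the N
observed clones with replacement (100 runs by default) and report the
standard deviation of each size's fraction.

## Clone-size windows

Clone sizes use a half-open window [t, t+40): every cell alive at the
window start contributes the number of its living descendants at the
window end (itself if undivided). A cell that divides exactly at the
window end contributes its daughters; a cell dying inside the window
contributes nothing; a clone any member of which is lost from tracking
inside the window is dropped for that window, as are zero-size clones
(founder died without progeny). The window slides in 1-hr steps and all
windows are pooled. Frame quantization makes exact boundary ties rare,
so these conventions matter little in practice, but they are fixed as
stated.

## Event-driven simulators

Both models advance division by division: the next divider is the
proliferating cell with the smallest remaining cycle time (a heap over
absolute division times), and a division replaces the mother by two
daughters whose states follow the mode probabilities above. Cycle times
are skew-normal; the default is calibrated by solving location and scale
(shape fixed at 4, a right tail as in measured cycle-time distributions)
so that the mean is 16.2 hr and P(C > 30 hr) = 7.1×10⁻⁷, giving
location ≈ 13.65 hr and scale ≈ 3.30 hr (sd ≈ 2.1 hr); non-positive
draws are resampled. Initial cells get ages uniform on [0, mean cycle),
redrawn if the age exceeds the drawn cycle.

Uniform model: the pool is unbounded; trajectories restart from the
initial condition on depletion (N = 0) or overgrowth (N ≥ 150 by
default), with events tallied and the clock running on (an option keeps
the absorbing state instead, used when checking against branching-process
calculations). At α = 0, φ = 0 every division is asymmetric and N is
exactly constant; at φ > 0 the variance after g synchronous generations
is φ·N₀·g, which the test suite verifies against an exact
branching-process convolution.

Compartment model: the niche is an ordered queue of exactly S positions
holding proliferating and non-proliferating cells; the differentiation
compartment is unbounded. A niche division inserts the daughters at the
mother's position (pushing higher indices distally) and transfers the
distalmost cell to the differentiation compartment unchanged in state; a
transferred proliferating cell still divides, with its mode drawn from
(α_d, φ) at division time — the daughters' states are set by the
environment the mother occupies when it divides. Rearrangements are
adjacent swaps, Poisson(r·S·Δt) per inter-division interval at uniformly
random positions j ∈ [0, S−2]. Depletion (no proliferating cell in
either compartment) and overgrowth (total proliferating ≥ 5× the initial
number) restart the trajectory from the initial condition with the same
stream of randomness, accumulating simulated time and event counts. The
initial condition places round(α_n·S) proliferating cells at random niche
positions (the rest non-proliferating) and max(0, N_target − round(α_n·S))
proliferating cells in the differentiation compartment; no burn-in is
discarded, since the transient is negligible over the ≥10⁵-hr runs used.

### Niche-size calibration and a known subtlety

The calibration picks the integer S minimizing
|α_n·S + N̄_d(S) − N_target|, where α_n·S is the analytic (well-mixed)
niche occupancy and N̄_d(S) is measured by short pilot simulations
(4,000 hr each, monotone in S, so integer bisection suffices). At
α_n = 1 the analytic term is exact — every niche cell proliferates — and
calibrated runs hold the target mean tightly (S = 21 for a target of 30
under the defaults).

At intermediate α_n with slow rearrangement (r·T = 1) the realized niche
occupancy sits *below* α_n·S: with φ near 1, symmetric divisions create
spatial clusters of like-fated cells, and because newborns are
proliferation-enriched relative to the standing population, the conveyor
delivers a proliferation-enriched stream to the distal end where cells
are expelled. The well-mixed closed form is recovered as r grows (the
test suite checks both behaviours). Consequences worth knowing: at
α_n = 0.5 the calibrated total mean undershoots the target by ~20–30%,
and the depletion rate there measures ~0.5 events per 10³ hr in this
implementation — the same order as, but below, the ≥1 per 10³ hr one
might expect at that operating point from well-mixed reasoning.
Extinction rates are exponentially sensitive to S and to the effective
niche occupancy, so this quantity depends on implementation conventions
(daughter placement, expulsion choice, calibration route) more than any
other statistic the package reports.

## The synthetic-data generator

The generator emulates the *statistics* of tracked crypts, not tissue
mechanics. Cells live on a cylinder of radius 20 µm whose axis lies
along +x (horizontal in the imaging frame, so the unwrapping angle is
informative); a few Paneth cells sit fixed near the base. Mothers choose
division modes from (α(δ), φ) where δ is their live Paneth link distance
computed with the same neighbour-graph rule the analysis uses, with
α = +0.67 for δ ≤ 1 and −0.67 beyond, φ = 0.98. Sister cycle times come
from a Gaussian copula over the skew-normal marginal (bivariate normal
with correlation 0.8 mapped through the quantile function), which yields
a Pearson correlation of ≈0.8 on the cycle scale. Non-proliferating
cells drift distally at 1.5 µm/hr; each division nudges every cell
distal to the mother by 0.6 µm (one cell-area of circumference), the
conveyor that clears arrested cells past the 60-µm boundary. Deaths
(probability 0.05 per newborn) and tracking losses (0.07, the observed
lost-cell fraction) are injected independently per cell. Frames are
sampled every 0.2 hr (the 12-min acquisition interval) with 0.25 µm
recording jitter.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: volume exclusion and neighbour mechanics
(cells may transiently overlap); sister-correlated death (observed death
pair fractions imply correlation; here deaths are independent, a
calibration knob rather than a claim); imaging artifacts beyond Gaussian
position jitter; crypt growth, budding or fission; and any feedback from
cell density onto fate. Parameter-recovery tests demonstrate that the
analysis inverts the generator's statistical structure, which shares the
measured values but not the full dependence structure of organoid
recordings.

## Problem sizes and tolerances in the test suite

Statistical tests fix their seeds and compare at 3 standard errors of
the relevant sampling distribution (computed at the true parameters), or
over replicates where a single draw would fail by chance a few percent of
the time. Simulation-based checks use 10⁵ simulated hours for
calibration and depletion statistics, 1.5×10⁴ hours per point for the
12-point-per-φ phase-diagram sweep (2,500-hr calibration pilots), and
eight 60-hr synthetic crypts (~700 divisions) for the full-loop recovery
of α(δ), φ and the sister cycle correlation; these sizes keep every
Monte-Carlo standard error comfortably below the tolerance it is compared
against. The bootstrap null uses the full 10⁵ iterations.

## Known limitations

- The niche queue is one-dimensional, as in the model it implements; no
  spatial tissue mechanics.
- The growth fit assumes the Uniform closed form with N₀, M₀ pinned to
  the first observation; no weighting or error model on the counts.
- Cousin statistics include any resolvable pair; no correction for
  families contributing several pairs.
- The depletion-rate caveat above: quantities driven by rare extinctions
  inherit the implementation conventions of the niche queue.
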