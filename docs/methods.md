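# Methods

## The model

`turbisim` simulates the transverse development of a seal maxilloturbinate
as a one-dimensional elastic tree of nodes embedded in a plane, growing
inside a circular cavity. The simulation alternates two steps.

**Relaxation.** Each node `i` (except the root, which is pinned to the
cavity wall) moves by

    r_i(t) = r_i(t-1) + k(t_i) * s_i,      k(t_i) = K * exp(-t_i / tau)

where `t_i` is the node's age, so tissue rigidifies exponentially on the
time scale `tau`. The displacement `s_i` sums three contributions:

* a chain spring to each tree neighbour with rest length `r0`,
  `s^n_ij = e_ij (|dr_ij| - r0)`;
* a purely repulsive interaction with every non-neighbour `j` inside its
  exclusion radius `m_j = max(2 r0, longest chain edge at j)`,
  `s^nn_ij = e_ij (|dr_ij| - m_j)`; the `m_j` floor enforces
  self-avoidance and the edge-length term keeps stretched chain segments
  impenetrable;
* a one-sided inward spring confining nodes to the cavity: zero deeper
  than `r0` from the wall, magnitude `|r_i| - (b - r0)` outside. The
  functional form of the wall term is a design choice (only "repulsive"
  is prescribed by the biology); a one-sided linear spring keeps it in
  the same family as the chain force and inert in the interior.

Next-nearest chain neighbours repel at `2 r0`, which is what gives the
chain its effective bending stiffness: a straight chain at spacing `r0`
is exactly at the exclusion distance, and any kink brings the pair inside
range.

**Growth.** One tip of the tree is chosen with probability inversely
proportional to the local node density; before the birth timestep `t_B`
the event is a fork (two children) with probability `p_fork`, otherwise a
single elongation. Children are placed on a circle of radius `r0 / 10`
around the tip so that new segments relax outward to `r0` under the
spring/repulsion balance rather than jumping into neighbouring tissue.
After `t_B` (birth), forking is disabled and only elongation continues —
branches are established prenatally, postnatal growth only lengthens
them.

**Boundary.** The bone area is tracked analytically during the run as
`A_b = L * w` (total backbone length times branch thickness). After every
growth event the cavity radius is set to
`b' = b * sqrt((1 - phi) / (1 - phi_target))`, clamped to never shrink
and capped at `B`, so the porosity `phi = 1 - A_b / (pi b^2)` stays at the
target while the cavity and the tissue grow together. The run starts from
a four-node chain rooted at the left wall, with `b(0)` chosen so the seed
already sits at the target porosity.

## Parameters

| name | default | meaning |
|---|---|---|
| `r0` | 1 (sets the unit) | chain rest length / half the exclusion distance |
| `K` | 0.1 | overdamped step gain; keeps per-sweep motion well below `r0` |
| `tau` | 4000 steps | rigidification time scale, same order as the run length |
| `t_max` | 4000 steps | run length (maps to relative age `t* = t / t_max`) |
| `t_B` | 2720 = 0.68 `t_max` | birth; the 0.68 comes from the rescaled skull length of a neonate specimen |
| `p_fork` | 0.25 | per-event fork probability before `t_B` (free parameter; produces Strahler numbers in the observed 6–7 range) |
| `phi_target` | 0.75 (seal) / 0.80 (monk) | target porosity |
| `B` | 55 `r0` | cavity radius cap; chosen so the structure naturally fills the disc at `t_max` (the packing radius `sqrt(2 L r0 / pi)` of ~4700 segments) |
| `w` | 0.50 (seal) / 0.40 (monk) | branch thickness, calibrated so the mean final rasterized porosity equals the target |

`r0` only sets the numerical scale. The porosity target, `t_B` and the
thickness calibration are the quantities with biological meaning.

### Local density radius

The growth-site rule is stated biologically as "inverse to the number of
nodes within `r0`". Taken literally it is inert: self-avoidance keeps all
non-neighbours at least `2 r0` away, so the `r0`-ball around any tip
contains exactly its parent and every tip receives the same weight (we
verified that trajectories with the rule on and off are bit-identical).
The counting ball is therefore taken at `3 r0`, the smallest radius that
can see the nearest neighbouring branch; this restores the documented
function of the rule (growth steered into open regions, and visibly
uneven growth when it is ablated).

## Numerics

Relaxation runs to quiescence rather than a fixed sweep count: after each
growth event, sweeps continue until the largest node step falls below
`1e-3 r0` (cap 50 per event). A fixed small sweep budget is unstable at
full scale — stress accumulates, edges stretch, their exclusion radii
grow, and the stronger repulsion stretches further edges until positions
diverge.

Because a single insertion perturbs the packing everywhere (a slowly
decaying displacement field), naive convergence sweeps touch every node
every step. The integrator instead keeps an **active set**: only nodes
whose environment changed are updated; a mover wakes everything inside
its interaction ball once its accumulated motion reaches `0.05 r0`, and
nodes whose step falls below the tolerance sleep. Forces are always
evaluated exactly (uniform spatial grid, with heavily stretched nodes on
an explicit side list); only the update schedule is lazy. A periodic
global wake (every 200 events) flushes residual stress.

Node-pair repulsion alone cannot strictly prevent branch crossings: on
the line through a stretched edge the restoring force normal to the gap
vanishes (a saddle), and a growing branch under pressure can creep
through. Two guards make the embedding's crossing number invariant:
moves are applied in index order and rejected if they would carry an
incident segment across any other segment (checked against current
positions), and new nodes redraw their placement angle (shrinking the
placement circle if needed) when the new segment would cross. With
avoidance enabled the final structures contain exactly zero crossings;
the ablated variant (`avoidance=False`) skips both guards and the
repulsion, accumulates crossings, and halts beyond 50 of them.

Degenerate geometry: exactly coincident non-neighbours repel along a
direction hashed deterministically from the node ids (never NaN,
reproducible); coincident chain neighbours contribute no spring force and
log a warning.

All stochastic draws (site, fork/elongate, angles) consume a single
per-run generator in a fixed order, so runs are bitwise reproducible from
the seed.

## Measurement pipeline

* **Rasterization** paints each edge as a stroke of width `w` with round
  caps by exact centre-in-stadium tests (unbiased area as resolution
  grows), at 16 px per `r0` by default, inside the final boundary disc.
* **Porosity, areas**: pixel counts inside the boundary mask.
* **Perimeter**: marching-squares contours of the one-pixel-Gaussian
  smoothed image; raw contours of hard binary edges overestimate length
  by ~5%, the smoothed ones are within 1% on discs and squares.
* **Hydraulic diameter** `D_h = 4 A_c / P`; rescaled by the span
  `S = 2B` for simulated sections (horizontal bone extent for external
  images).
* **Complexity** `C_x = ln(P^2 / 4 pi) / ln(A_c)` is evaluated in pixel
  units of the analysed image. The quantity is unit-dependent through the
  logarithms; pixels are the convention under which published scan and
  model values are mutually consistent, and the pixel size is recorded
  with every result.
* **Backbone (path) dimension**: sample vertex pairs, compute tree
  geodesic vs Euclidean distance. Conditioned on geodesic length `l` the
  displacement scales as `l^(1/d_m)`, so we regress log-Euclidean on
  log-geodesic and report the inverse slope; the naive regression the
  other way round is dominated by pairs that are close in space but far
  along the tree and can even fall below 1. A straight chain gives
  exactly 1.0.
* **Horton–Strahler**: branches ordered by iterative leaf-pruning (the
  round number is the order), which provably matches the recursive
  children-max/+1 rule when the root has degree 1 (it always does here:
  the wall node never forks). `R_B` and `R_L` are `exp(|slope|)` of
  least-squares fits of `ln N_w` and `ln mean-length_w` against order
  over all orders. Image skeletons may contain loops; they are broken by
  keeping the maximum spanning tree (dropping the shortest bridge of each
  cycle) and the removed length fraction is reported.
* **Skeletonization** of binary sections: morphological thinning of the
  largest bone component; junction pixel clusters are merged into single
  vertices. Sections whose bone connectivity is below 0.9 are refused —
  fragmented scans produce skeletons dominated by noise.

## Comparators

*DLA*: on-lattice, central seed, ring-launched walkers with long radial
jumps while far from the cluster (hitting distribution unchanged),
8-neighbour sticking. Mass–radius dimension of 30k-site clusters is
1.71–1.73, the known value for the process. Note that a planar DLA
cluster cannot actually be porosity-matched at scale: with mass
dimension < 2 its enclosing-disc air fraction rises towards 1 as it
grows, so the width-contrast comparison uses clusters of comparable
extent instead.

*BARW*: persistent random-walk tips (angular noise 0.15/step) that branch
at 0.25/step at ±70° and annihilate within 2 `r0` of any deposited trail
or at the domain wall; a 5-step grace period after branching lets a new
tip clear its parent and sibling. The process is near-critical
(extinction vs explosion), so the calibrated parameter is the step
budget: 11 000 tip-steps gives a median thickened-trail porosity of 0.75
across seeds, matching the main model's target. Porosity spread across
seeds remains wide — inherent to the process, and part of the contrast
with the width-regulated growth model.

## What the synthetic data does and does not show

Channel-width regulation is quantified as the coefficient of variation
of the air distance-transform ridge values (local channel half-widths):
the growth model sits near 0.6 while matched BARW and extent-matched DLA
structures exceed 2, because neither regulates its void sizes.

All quantitative claims are measured on simulated structures and
deterministic geometric fixtures; no tomograms ship with the package.
The fixtures (discs, annuli, paths, perfect binary trees, combs,
meanders) have closed-form metric values and validate the estimators, not
the biology. Passing tests show that the implemented mechanism produces
labyrinths whose porosity, channel geometry, complexity, path dimension
and branching statistics sit in the published ranges — they do not show
that real turbinate growth uses these mechanisms, and real cross-sections
additionally have thickness variation along branches, mucosa, noise and
partial connectivity that the model deliberately omits.

## Known limitations

* Strictly 2-D; no rostro-caudal coupling, no bone resorption, no
  mucosa, constant branch thickness.
* Simulated Strahler numbers sit at the top of the observed 6–7 range
  (mean 7.0) and branch-length ratios at the low end (~1.46 vs 1.7–1.8):
  the implemented fork process (uniform fork probability at
  density-selected tips) produces somewhat more balanced trees than the
  reference measurements; the published fork-scheduling details are not
  sufficient to close this gap without tuning to the outcome.
* The monk-seal rescaled hydraulic diameter is structurally tied to
  `~2 phi s / 2B` with branch spacing `s` pinned near the exclusion
  distance `2 r0`; at fixed `t_max` and `B`, raising the porosity target
  from 0.75 to 0.80 can raise `D_h*` by only ~7%, not the ~88% separating
  the published seal and monk model values. The monk batch therefore
  reports `D_h*` around 0.028–0.029 rather than 0.047.
* Relaxation effort (tolerance, wake quantum) trades run time against
  residual stress; the shipped defaults keep edge-length tails and all
  headline metrics stable while a full-scale run takes tens of seconds.
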