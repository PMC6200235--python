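# Methods

## Model

The simulator couples two processes on a square domain of side `l`
(default 1), discretised into `N_x × N_y` binary lattice cells
(`Δx = l/N_x`, default 0.01):

**Wax supply (attachers).** One dollop of wax attaches per time unit:
every off-cell 4-adjacent to an on-cell is a growth candidate, tagged by
the axis of its on-neighbour(s), and one candidate switches on per step.
Anisotropy is class-first: with probability `p_x` the new cell is drawn
uniformly from the x-tagged class, else from the y-tagged class, falling
back to the other class only when the chosen one is empty. A cell with
on-neighbours along both axes belongs to both classes, which keeps
`p_x = 0.5` exactly isotropic in distribution over axes and makes
`p_x = 1` freeze the y-extent (the first cell of a new row can only be
y-tagged). The candidate-weighted alternative (each cell weighted by its
adjacency types) was measured to produce *less* elongation at every
`p_x` and was not adopted. Growth adjacency does not wrap: the cluster
stops at the lattice edge. Cells under an excavation-zone footprint
cannot receive wax.

**Wax removal (excavators).** Each excavation zone (EZ) is the area the
worker's rotating head can sweep: a forward half-disc of radius
`r = w_ex/2` centred on the pose point plus a backward `w_ex × L`
rectangle, `L = h_ex − w_ex/2`. Rotation is always about the half-disc
centre. All EZs share geometry and speed; their motion is periodic
(toroidal), and footprint rasterisation and ray sampling wrap
accordingly — only growth adjacency is planar. The pose updates once per
time unit by these rules, evaluated in a freshly randomised EZ order:

1. *Free flight.* No wax within the sensing band: advance `v_ex` along
   the heading.
2. *Approach.* Wax sensed within `d_s` of the front arc: rotate toward
   the nearest sensed bearing by at most `ω_ex`, then advance if still
   out of contact.
3. *Dig.* Frontal contact with wax at least `d_w` thick everywhere
   across the front: advance `v_ex` into it; every on-cell covered by
   the new footprint is excavated (removal-on-coverage — excavation is
   progressive, not an instantaneous clearing).
4. *Thin-wall refusal.* If any contacting probe ray sees wax thinner
   than `d_w`, the EZ does not advance. It rotates `ω_ex` toward the
   side whose probed wax is thickest, but only if that rotation is
   admissible (would nowhere excavate a sub-`d_w` wall) *and* actually
   offers diggable (≥ `d_w`) wax. Otherwise it halts in place (local
   equilibrium). Halted EZs re-evaluate every step and resume when
   growth thickens their surroundings.

The thinness refusal is applied across the whole front arc, not just on
the axis: the sensing band spans the arc, and a centre-ray-only gate
would let the flanks of the advancing half-disc slice through walls the
centre never saw, fragmenting the cluster (verified to happen; the
arc-wide gate keeps the cluster 4-connected, which is the point of the
minimum-thickness rule).

**Sensing.** Nine probe rays leave the front arc at bearings
`heading + φ`, `φ ∈ {−π/2, −3π/8, …, +π/2}` — a concrete stand-in for
the antennae; the spacing samples the arc at sub-`d_w` resolution at
canonical parameters. Rays sample the lattice every `Δx/4` (configurable
via `ray_step_frac`), fine enough that a `d_w = 2`-cell wall cannot be
aliased away. A ray reports the gap to the first on sample and the
length of the contiguous on-run there. "Contact" means a gap of at most
`v_ex + Δx/4`.

**Collisions.** Collisions are head-initiated: two overlapping front
half-discs (or mutual head-into-body contact) is a head-on collision,
one head inside the other's rectangle is a head-into-body collision, and
rectangle-rectangle overlap alone is no collision. Working EZs
(approaching, digging or halted) are never evicted: if exactly one of a
colliding pair is free, the free one teleports; for free-free pairs a
head-into-body hit evicts the struck EZ (configurable to the striker,
since the source rules are ambiguous there) and a head-on hit evicts one
at random. A teleported EZ reappears at a uniformly random point on the
domain edge with an inward heading; the insertion point is rejection-
sampled until the footprint overlaps neither another EZ nor wax (up to
50 tries) — rematerialising on top of either is unphysical, and without
the rejection the edge ring accumulates colliding EZs in a self-feeding
teleport cascade.

**Scheduling.** Per time unit: one growth event (excluding all EZ
footprints), then every EZ's behaviour rule in randomised order with
immediate excavation, then collision resolution, then metrics. A single
seeded generator drives all randomness, so runs are bit-reproducible.

## Parameters

| key | default | meaning |
|---|---|---|
| `l` | 1.0 | domain side (abstract length unit) |
| `N_x = N_y` | 100 | lattice partitions |
| `w_ex` | 0.1 l | EZ width (worker-scale) |
| `h_ex` | 0.15 l | EZ length; `3·w_ex/2` matches the ~1:2 body ratio |
| `d_s` | 0.02 l | antenna sensing distance (= `d_w` for simplicity) |
| `d_w` | 0.02 l | minimum wax thickness, `w_ex/5` |
| `sigma` | 0.15 | EZ area fraction; sociality/worker-density proxy |
| `p_x` | 0.5 | probability of x-directed growth |
| `diag_coeff` | √2 | coefficient in `v_ex = (c/5)Δx`, `ω_ex = cΔx/L` |
| `seed_wax_cells` | 1 | half-width of the central seed block (3×3 cells) |

Derived: `ez_area = πw²/8 + w(h − w/2)` ≈ 0.01393, `n_ez =
round(σl²/ez_area)` = 11, `v_ex ≈ 0.00283` (0.28 cells/step), `ω_ex ≈
0.141 rad/step`.

The `diag_coeff` question is genuinely open: the speed formulas can be
read with the coefficient as the lattice-cell diagonal √2 or as a
literal 2. Both are runnable; √2 is the default. An ensemble comparison
of tripod-emergence medians showed no decisive difference (≈ 455 vs
≈ 540). The EZ count and the initial wax amount are likewise not fixed
by the source material: `n_ez` is derived from `σ` by rounding, and the
3×3-cell seed was chosen comparable to `d_w` (2 cells) so the thickness
rule is meaningful from the start. Initial EZ poses are uniform,
rejection-sampled to overlap neither each other nor the seed — an EZ
dropped onto the seed would excavate it at t = 0 and the run could never
recover, since growth cannot restart from an empty lattice.

## Pattern detectors

The source model's pattern claims are visual; the detectors here are the
package's own operationalisations, with every threshold an explicit,
documented default:

* **Tripod**: at least three EZs in the ENGAGED or EQUILIBRIUM state
  whose footprints touch the main (largest 4-connected) cluster dilated
  by `d_s`, three of which sit at bearings about the cluster centroid
  pairwise separated by ≥ π/2.
* **Branch points**: junctions (≥ 3 neighbours, 8-connectivity) of the
  morphological skeleton of the cluster, merged within `d_w`.
* **1D connection**: ≥ 2 branch points *and* bounding-box aspect ratio
  (x-extent/y-extent of the main cluster) ≥ 2 *and* x-extent ≥ 3·`h_ex`.
  The extent floor rejects juvenile clusters — a chain of tripods cannot
  be shorter than about two tripod units (one unit ≈ the `2·h_ex` dig
  scale) — without which the two-term criterion fires on ~70-cell
  transients near t ≈ 70, far before any tripod exists.

Detectors are pure functions of the state and are evaluated every step.

## What the simulations show, and known limitations

At canonical parameters the isotropic run develops carved junction
morphology (visually tripod-like) around t ≈ 200–250, and the
EZ-configuration tripod detector fires at a median of roughly 450–530
over ≥ 20 seeds: about half of that lag is search time (the third EZ
reaches the cluster between t ≈ 170 and 550 — ballistic search
interrupted by frequent collision teleports is slow at σ = 0.15), and
half is the detector's bearing-spread requirement, since EZs park where
they arrive and can bunch. With `p_x = 0.7` the cluster forms elongated
branched chains, but its bounding-box aspect ratio crosses 2 before
t = 2000 in only ~40 % of seeds (those fire between ≈ 460 and 1800);
class-first anisotropic Eden growth alone reaches only ≈ 1.7 at this
horizon, so the aspect threshold is the binding term. `p_x = 0.8`
crosses it intermittently. Because the fire fraction hovers near one
half, ensemble medians are knife-edge quantities: different 21-seed
ensembles give tripod medians between ≈ 455 and 665 and 1D medians
between ≈ 840 and the censored horizon. Emergence-time medians from
this simulator should therefore be read as upper bounds relative to a
visual judgment of the same morphology.

The net wax growth rate is U-shaped rather than monotone declining:
≈ 0.8 cells per step while the cluster is still unattended, ≈ 0.4
during the excavation-dominated phase (t ≈ 200–600), recovering toward
the supply rate late, once every zone is parked against a protected
thin wall and can only re-excavate regrowth in its own sector while the
cluster perimeter keeps lengthening. A monotone decline would require
excavation pressure to scale with the perimeter, which a fixed census
of never-evicted zones cannot provide.

Other modelled simplifications: excavated wax vanishes (no transport or
reuse); supply is a constant one cell per time unit regardless of how
many attachers the density nominally represents; EZs in wax move
ballistically until stopped; halted EZs are never retired; pairs of
non-free EZs that come to overlap are tolerated rather than teleported
(head-initiated rules do not cover them). The synthetic dynamics are 2D
only — the tetrapod (3D) case is a straightforward but unimplemented
extension. None of the emulated behaviour includes real-bee features
such as heterogeneous wax volumes, antenna physiology, or supply-rate
regulation, so passing tests validate the self-organisation mechanism,
not quantitative bee behaviour.

## Numerical choices

Ray sampling at `Δx/4` bounds gap/run errors by one sample; admissibility
treats only gap-0 rays (already embedded in wax) as excavating. Cell
membership of a footprint uses cell centres, giving ≤ 5 % area error at
`N = 100`, halving-ish per resolution doubling. Collision classification
reuses the rasterised head/body cell sets, so its resolution is one
lattice cell. The `n_ez` rounding is half-up. Ties in the thin-wall
rotation direction are broken by the run's RNG stream; all other
detector and policy evaluations are deterministic. Problem sizes used by
the test suite and the acceptance script (ensembles of 20–21 seeds,
horizons of 800–2000 steps for the stochastic claims, 5000 steps for the
exact growth laws) keep a full verification run in the minutes range on
a single core.
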