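# waxcomb

An agent-based simulator of the **first stage of honeycomb construction**:
how worker honeybees, following purely local rules, turn a featureless
dollop of wax into the three-armed (tripod) junctions that seed the comb,
and how those junctions connect into a line.

The model splits the workforce into two roles:

* **Attachers** supply wax. They are abstracted into a stochastic lattice
  growth rule (Eden growth): each time unit, one off-cell adjacent to the
  wax cluster switches on. A parameter `p_x ∈ [0.5, 1]` biases growth
  toward the x-axis (`p_x = 0.5` isotropic, `p_x = 1` no y-growth at all).
* **Excavators** remove wax. Each is abstracted into an *excavation zone*
  (EZ): a semicircle of radius `w_ex/2` (the sweep of the worker's head)
  on the front of a `w_ex × (h_ex − w_ex/2)` rectangle. EZs move at speed
  `v_ex`, rotate about the semicircle centre at `ω_ex`, sense wax within
  a distance `d_s` of the front arc, and — crucially — **refuse to dig
  through any wall thinner than `d_w`**. An EZ surrounded by sub-`d_w`
  walls halts in place (local equilibrium). EZ motion is periodic; when
  two EZs touch head-first, one is teleported to a random edge point, so
  the EZ count is conserved.

The competition of the two currents (one wax cell in per time unit, many
cells out wherever an EZ digs) is a dissipative process: thin walls that
no excavator may pierce are the stable residue, and with three halted
excavators around a young cluster those walls form a tripod — the 2D
projection of the tetrapod building block of real comb. With anisotropic
supply the tripods connect along x into a 1D chain.

Canonical parameters (unit square, `N = 100` lattice): `w_ex = 0.1`,
`h_ex = 0.15`, `d_s = d_w = 0.02`, area fraction `σ = 0.15` (≈ 11 EZs),
`v_ex = √2/5·Δx`, `ω_ex = √2·Δx/(h_ex − w_ex/2)`.

## Worked example

```python
import waxcomb as w

cfg = w.validate_config({"t_max": 1000, "rng_seed": 1})     # Table defaults
state, record, snaps = w.simulate(cfg, snapshot_every=250)

print("wax cells:", record.column("wax_count")[-1])
print("halted EZs:", record.column("n_equilibrium")[-1])
print("tripod first seen at t =", w.first_detection_time(record, "tripod_flag"))
```

prints (seed 1):

```
wax cells: 693
halted EZs: 5
tripod first seen at t = 371
```

i.e. after 1000 time units the cluster holds 693 wax cells (1009 supplied,
the rest excavated), five of the eleven excavation zones have halted
against walls they may not pierce, and the tripod configuration — three
engaged/halted EZs spread at least a quarter-turn apart around the
cluster — was first detected at t = 371.

The same run from a shell, with PNG/PGM frames and CSV metrics:

```bash
waxcomb simulate --seed 1 --t-max 1000 --px 0.5 --out runs/iso
waxcomb render --run runs/iso --center-ninth
```

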