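"""Simulation loop: wax supply, EZ updates, collisions, periodic boundary.

One time unit is the average wax-supply interval: each step attaches one
dollop of wax (a single Eden growth event, excluding cells under any EZ
footprint), then updates every EZ in a freshly randomised order, then
resolves EZ-EZ collisions by teleporting one of each colliding pair to a
random point on the domain edge.  All randomness flows through a single
seeded generator, so identical configurations give identical runs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .config import DerivedKinematics, SimulationConfig, derive_kinematics
from .excavator import (EZState, ExcavationZone, behave, footprint_parts)
from .grid import WaxGrid, grow_one, make_seeded_grid, wax_count
from .metrics import (MetricsRecord, branch_points, cluster_extents,
                      tripod_emerged)

__all__ = [
    "SimulationState",
    "classify_collision",
    "teleport",
    "resolve_collisions",
    "step",
    "simulate",
]

logger = logging.getLogger("waxcomb")

_WORKING = (EZState.APPROACH, EZState.ENGAGED, EZState.EQUILIBRIUM)


@dataclass
class SimulationState:
    """Full mutable state of one run."""

    t: int
    grid: WaxGrid
    ezs: list[ExcavationZone]
    rng: np.random.Generator
    config: SimulationConfig
    kin: DerivedKinematics
    record: MetricsRecord = field(default_factory=MetricsRecord)
    events: list[tuple] = field(default_factory=list)  # (t, id, x, y, theta, state, n_removed)
    compute_detectors: bool = True
    _fp_cache: dict = field(default_factory=dict, repr=False)


def _footprint_sets(state: SimulationState, ez: ExcavationZone):
    """Cached (head, body) flat-index cell sets for collision tests."""
    key = (ez.id, float(ez.center[0]), float(ez.center[1]), ez.heading)
    hit = state._fp_cache.get(ez.id)
    if hit is not None and hit[0] == key:
        return hit[1], hit[2]
    head, body = footprint_parts(ez, state.config, state.kin)
    nx = state.grid.nx
    hs = frozenset((head[:, 1] * nx + head[:, 0]).tolist())
    bs = frozenset((body[:, 1] * nx + body[:, 0]).tolist())
    state._fp_cache[ez.id] = (key, hs, bs)
    return hs, bs


def _collision_detail(state: SimulationState, a: ExcavationZone,
                      b: ExcavationZone):
    """(kind, struck_candidates) for a pair; kind None when no head overlap.

    Head-head (or mutual head-body) contact -> "head_to_head" with both
    EZs candidates for eviction; a single head-into-body contact ->
    "head_to_body" with (striker, struck) resolved.  Overlap of the two
    rectangles alone is not a collision: the model's encounters are all
    head-initiated.
    """
    ha, ba = _footprint_sets(state, a)
    hb, bb = _footprint_sets(state, b)
    if ha & hb:
        return "head_to_head", (a, b)
    a_hits_b = bool(ha & bb)
    b_hits_a = bool(hb & ba)
    if a_hits_b and b_hits_a:
        return "head_to_head", (a, b)
    if a_hits_b:
        return "head_to_body", (a, b)  # a strikes, b struck
    if b_hits_a:
        return "head_to_body", (b, a)
    return None, None


def classify_collision(a: ExcavationZone, b: ExcavationZone,
                       config: SimulationConfig, kin: DerivedKinematics,
                       grid: WaxGrid | None = None) -> str | None:
    """Classify an EZ pair: None, "head_to_body" or "head_to_head".

    Distances use the periodic metric via the wrapped footprint
    rasterisation.  ``grid`` supplies the lattice geometry; when omitted
    a throwaway lattice of the configured size is used.
    """
    if grid is None:
        grid = WaxGrid(np.zeros((config.N_y, config.N_x), dtype=bool),
                       kin.dx, kin.dy)
    state = SimulationState(0, grid, [], np.random.default_rng(0), config, kin)
    kind, _ = _collision_detail(state, a, b)
    return kind


def teleport(ez: ExcavationZone, rng: np.random.Generator,
             config: SimulationConfig) -> ExcavationZone:
    """Reinsert an EZ at a uniformly random point on the domain edge.

    The heading is uniform over the inward-pointing half-plane and the
    state resets to FREE.
    """
    l = config.l
    u = rng.random() * 4 * l
    side, pos = int(u // l), u % l
    if side == 0:       # bottom edge, inward normal +y
        center, normal = (pos, 0.0), math.pi / 2
    elif side == 1:     # right edge, inward normal -x
        center, normal = (l, pos), math.pi
    elif side == 2:     # top edge, inward normal -y
        center, normal = (pos, l), -math.pi / 2
    else:               # left edge, inward normal +x
        center, normal = (0.0, pos), 0.0
    heading = normal + (rng.random() - 0.5) * math.pi
    return replace(ez, center=np.array(center), heading=heading % (2 * math.pi),
                   state=EZState.FREE)


def _reinsert(state: SimulationState, ez: ExcavationZone,
              tries: int = 50) -> ExcavationZone:
    """Teleport an EZ to an edge point where its footprint fits.

    Candidate poses are drawn exactly as in :func:`teleport`; a pose is
    accepted when the footprint overlaps neither another EZ nor the wax
    (rematerialising on top of either would be unphysical and feeds a
    teleport cascade along the crowded edge ring).  After ``tries``
    rejections the last draw is accepted and the collision loop deals
    with any remaining overlap.
    """
    state._fp_cache.pop(ez.id, None)
    others = [o for o in state.ezs if o.id != ez.id]
    new = ez
    for _ in range(tries):
        new = teleport(ez, state.rng, state.config)
        state._fp_cache.pop(ez.id, None)
        head, body = _footprint_sets(state, new)
        cells = head | body
        flat = np.fromiter(cells, dtype=np.intp)
        if flat.size and state.grid.occupancy.ravel()[flat].any():
            continue
        clash = False
        for o in others:
            oh, ob = _footprint_sets(state, o)
            if cells & (oh | ob):
                clash = True
                break
        if not clash:
            break
    state._fp_cache.pop(ez.id, None)
    return new


def resolve_collisions(state: SimulationState) -> SimulationState:
    """Teleport one EZ of each colliding pair until no head contact remains.

    Working EZs (approaching, engaged or halted) are never evicted: if
    exactly one of a colliding pair is FREE, the FREE one teleports.  For
    FREE-FREE pairs a head-into-body hit evicts the struck EZ (the
    striker, if ``body_hit_teleports_struck`` is False) and a head-on hit
    evicts one of the two uniformly at random.  Pairs in which neither EZ
    is FREE are left in place.
    """
    n = len(state.ezs)
    if n < 2:
        return state
    for _ in range(n * n + 1):
        actionable = []
        for ia, ib in itertools.combinations(range(n), 2):
            a, b = state.ezs[ia], state.ezs[ib]
            kind, detail = _collision_detail(state, a, b)
            if kind is None:
                continue
            free = [ez for ez in (a, b) if ez.state == EZState.FREE]
            if not free:
                continue  # working EZs are never evicted
            actionable.append((ia, ib, kind, detail))
        if not actionable:
            return state
        order = state.rng.permutation(len(actionable))
        for k in order:
            ia, ib, _, _ = actionable[k]
            a, b = state.ezs[ia], state.ezs[ib]
            kind, detail = _collision_detail(state, a, b)  # re-check: poses may have changed
            if kind is None:
                continue
            a_free = a.state == EZState.FREE
            b_free = b.state == EZState.FREE
            if a_free and not b_free:
                victim = ia
            elif b_free and not a_free:
                victim = ib
            elif a_free and b_free:
                if kind == "head_to_body":
                    striker, struck = detail
                    target = struck if state.config.body_hit_teleports_struck else striker
                    victim = ia if target is a else ib
                else:
                    victim = (ia, ib)[int(state.rng.integers(2))]
            else:
                continue
            old = state.ezs[victim]
            state.ezs[victim] = _reinsert(state, old)
            logger.info("t=%d teleport EZ %d (%s)", state.t, old.id, kind)
    raise RuntimeError("EZ overlap not resolvable; geometry inconsistency")


def _append_metrics(state: SimulationState, removed: int) -> None:
    cfg, kin, grid = state.config, state.kin, state.grid
    tallies = {s: 0 for s in EZState}
    for ez in state.ezs:
        tallies[ez.state] += 1
    if state.compute_detectors:
        tri = tripod_emerged(grid, state.ezs, cfg, kin)
        bp = branch_points(grid, merge_dist=cfg.d_w)
        try:
            xe, ye = cluster_extents(grid)
            ar = xe / ye
        except ValueError:
            xe, ar = math.nan, math.nan
    else:
        tri, bp, ar, xe = False, 0, math.nan, math.nan
    state.record.append(
        t=state.t, wax_count=wax_count(grid),
        n_free=tallies[EZState.FREE], n_approach=tallies[EZState.APPROACH],
        n_engaged=tallies[EZState.ENGAGED],
        n_equilibrium=tallies[EZState.EQUILIBRIUM],
        cells_removed_this_step=removed, tripod_flag=tri,
        branch_point_count=bp, aspect_ratio=ar, x_extent=xe)


def _exclusion_mask(state: SimulationState) -> np.ndarray | None:
    if not state.ezs:
        return None
    mask = np.zeros_like(state.grid.occupancy)
    for ez in state.ezs:
        head, body = footprint_parts(ez, state.config, state.kin)
        for part in (head, body):
            mask[part[:, 1], part[:, 0]] = True
    return mask


def step(state: SimulationState) -> SimulationState:
    """Advance the simulation by one time unit (in place)."""
    cfg, kin = state.config, state.kin
    # 1. One dollop of wax, never under an EZ footprint.
    grow_one(state.grid, cfg.p_x, state.rng, _exclusion_mask(state))
    # 2. EZ behaviour in randomised order; excavation applied immediately.
    removed_total = 0
    order = state.rng.permutation(len(state.ezs))
    for idx in order:
        ez = state.ezs[idx]
        new_ez, (ii, jj) = behave(ez, state.grid, state.rng, cfg, kin)
        n_rm = state.grid.set_off(ii, jj) if len(ii) else 0
        removed_total += n_rm
        if new_ez.state != ez.state and new_ez.state == EZState.EQUILIBRIUM:
            logger.info("t=%d EZ %d halts (local equilibrium)", state.t, ez.id)
        elif ez.state == EZState.EQUILIBRIUM and new_ez.state != EZState.EQUILIBRIUM:
            logger.info("t=%d EZ %d resumes (%s)", state.t, ez.id, new_ez.state.value)
        state.ezs[idx] = new_ez
        state._fp_cache.pop(ez.id, None)
        state.events.append((state.t + 1, ez.id, float(new_ez.center[0]),
                             float(new_ez.center[1]), new_ez.heading,
                             new_ez.state.value, n_rm))
    # 3. Collisions.
    resolve_collisions(state)
    # 4. Bookkeeping.
    state.t += 1
    _append_metrics(state, removed_total)
    return state


def _place_ezs(state: SimulationState) -> None:
    """Random non-overlapping FREE poses, clear of each other and the wax."""
    cfg, kin = state.config, state.kin
    for k in range(kin.n_ez):
        for attempt in range(10_000):
            center = state.rng.random(2) * cfg.l
            heading = state.rng.random() * 2 * math.pi
            ez = ExcavationZone(id=k, center=center, heading=heading)
            head, body = _footprint_sets(state, ez)
            cells = head | body
            occ_flat = np.fromiter(cells, dtype=np.intp)
            if occ_flat.size and state.grid.occupancy.ravel()[occ_flat].any():
                state._fp_cache.pop(k, None)
                continue
            clash = False
            for other in state.ezs:
                oh, ob = _footprint_sets(state, other)
                if cells & (oh | ob):
                    clash = True
                    break
            if not clash:
                state.ezs.append(ez)
                break
            state._fp_cache.pop(k, None)
        else:
            raise RuntimeError(
                f"could not place EZ {k} without overlap in 10000 attempts "
                f"(area fraction sigma={cfg.sigma} too large for the domain)")


def simulate(config: SimulationConfig, *, until=None, snapshot_every: int | None = None,
             compute_detectors: bool = True):
    """Run a full simulation from the seeded grid.

    Parameters
    ----------
    config : SimulationConfig
        Validated run configuration; ``config.rng_seed`` seeds the single
        random stream, making the run fully reproducible.
    until : callable, optional
        ``until(state) -> bool`` checked after every step; True stops the
        run early (used e.g. to stop at first pattern detection).
    snapshot_every : int, optional
        Record a copy of the occupancy lattice every so many steps
        (always including t=0 and the final step).
    compute_detectors : bool
        Evaluate the pattern detectors each step (disable for long
        property runs where only the basic columns are needed).

    Returns
    -------
    (state, record, snapshots)
        Final state, its metrics record, and a list of ``(t, occupancy)``
        snapshot pairs.
    """
    kin = derive_kinematics(config)
    rng = np.random.default_rng(config.rng_seed)
    grid = make_seeded_grid(config)
    state = SimulationState(t=0, grid=grid, ezs=[], rng=rng, config=config,
                            kin=kin, compute_detectors=compute_detectors)
    _place_ezs(state)
    _append_metrics(state, 0)
    snapshots = []
    if snapshot_every:
        snapshots.append((0, grid.occupancy.copy()))
    for _ in range(config.t_max):
        step(state)
        if snapshot_every and state.t % snapshot_every == 0:
            snapshots.append((state.t, state.grid.occupancy.copy()))
        if until is not None and until(state):
            break
    if snapshot_every and (not snapshots or snapshots[-1][0] != state.t):
        snapshots.append((state.t, state.grid.occupancy.copy()))
    return state, state.record, snapshots
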