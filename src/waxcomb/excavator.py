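"""Excavation-zone agents: geometry, sensing, and the digging policy.

An excavation zone (EZ) abstracts the region swept by an excavator
worker's head: a semicircle of radius ``w_ex / 2`` on the forward side of
the rotation centre plus a rectangle of width ``w_ex`` extending backward
a length ``L = h_ex - w_ex / 2``.  The pose is the continuous centre of
the semicircle and a heading angle; rotation is always about the centre.

Sensing is realised by 9 probe rays cast outward from the front arc at
bearings ``heading + phi``, ``phi in {-pi/2, -3pi/8, ..., +pi/2}`` — a
concrete stand-in for the antennae.  Each probe reports the gap to the
nearest wax and the thickness (contiguous run) of that wax, which drive
the behavioural rules:

* wax sensed within ``d_s``  -> turn toward it and approach;
* wax ahead thicker than the minimum thickness ``d_w`` -> advance into
  it, excavating the cells the footprint newly covers;
* wax ahead thinner than ``d_w`` -> refuse to advance; rotate toward the
  thickest admissible side, where a rotation is admissible only if it
  would nowhere leave a wall thinner than ``d_w``;
* no admissible rotation -> halt in place (local equilibrium).

A halted EZ re-runs the policy every step and resumes digging once
growth has thickened its surroundings.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .config import DerivedKinematics, SimulationConfig
from .grid import WaxGrid, ray_runs

__all__ = [
    "EZState",
    "ExcavationZone",
    "PROBE_OFFSETS",
    "footprint_cells",
    "footprint_parts",
    "sense_wax",
    "front_thickness",
    "rotation_admissible",
    "behave",
]

#: Probe bearings relative to the heading, pi/8 apart over [-pi/2, +pi/2].
PROBE_OFFSETS = np.linspace(-math.pi / 2, math.pi / 2, 9)
_FRONT = len(PROBE_OFFSETS) // 2  # index of the on-axis probe


class EZState(enum.Enum):
    FREE = "free"
    APPROACH = "approach"
    ENGAGED = "engaged"
    EQUILIBRIUM = "equilibrium"


@dataclass
class ExcavationZone:
    """Pose and behavioural state of one excavation zone."""

    id: int
    center: np.ndarray  # (2,) floats, length units
    heading: float      # radians in [0, 2*pi)
    state: EZState = EZState.FREE
    _fp: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.heading = float(self.heading) % (2 * math.pi)


def _unit(theta: float) -> np.ndarray:
    return np.array([math.cos(theta), math.sin(theta)])


def _wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]."""
    return -((-a + math.pi) % (2 * math.pi) - math.pi)


def footprint_parts(ez: ExcavationZone, config: SimulationConfig,
                    kin: DerivedKinematics):
    """Rasterised footprint split into head and body cells.

    Returns ``(head, body)`` where each part is an ``(m, 2)`` int array of
    ``(i, j)`` lattice cells whose centres lie inside the semicircle
    (head) or the rectangle (body), with periodic wrapping.
    """
    r = config.w_ex / 2.0
    L = config.h_ex - config.w_ex / 2.0
    if config.w_ex <= 0:
        z = np.empty((0, 2), dtype=np.intp)
        return z, z
    cx, cy = float(ez.center[0]), float(ez.center[1])
    key = (cx, cy, ez.heading, config.w_ex, config.h_ex, kin.dx)
    if ez._fp is not None and ez._fp[0] == key:
        return ez._fp[1], ez._fp[2]
    c, s = math.cos(ez.heading), math.sin(ez.heading)
    R = max(r, math.hypot(L, r))  # farthest footprint point from the centre
    i0 = math.floor((cx - R) / kin.dx)
    i1 = math.floor((cx + R) / kin.dx)
    j0 = math.floor((cy - R) / kin.dy)
    j1 = math.floor((cy + R) / kin.dy)
    relx = (np.arange(i0, i1 + 1) + 0.5) * kin.dx - cx   # (w,)
    rely = (np.arange(j0, j1 + 1) + 0.5) * kin.dy - cy   # (h,)
    u = relx[None, :] * c + rely[:, None] * s            # (h, w)
    v = relx[None, :] * -s + rely[:, None] * c
    head = (u >= 0) & (u * u + v * v <= r * r)
    body = (u < 0) & (u >= -L) & (np.abs(v) <= r)

    def pack(mask):
        jj, ii = np.nonzero(mask)
        out = np.empty((ii.size, 2), dtype=np.intp)
        out[:, 0] = (ii + i0) % config.N_x
        out[:, 1] = (jj + j0) % config.N_y
        return out

    parts = pack(head), pack(body)
    ez._fp = (key, parts[0], parts[1])
    return parts


def footprint_cells(ez: ExcavationZone, config: SimulationConfig,
                    kin: DerivedKinematics) -> set[tuple[int, int]]:
    """Set of ``(i, j)`` lattice cells covered by the EZ footprint."""
    head, body = footprint_parts(ez, config, kin)
    cells = {(int(i), int(j)) for i, j in head}
    cells.update((int(i), int(j)) for i, j in body)
    return cells


def _probe(ez: ExcavationZone, grid: WaxGrid, config: SimulationConfig,
           kin: DerivedKinematics, heading: float | None = None):
    """Cast the 9 probe rays from the front arc.

    Returns ``(bearings, gaps, runs)``; gaps are measured from the arc
    surface outward, with horizon ``d_s + h_ex`` so that wall thickness
    is measurable behind a sensed gap.
    """
    th = ez.heading if heading is None else heading
    bearings = th + PROBE_OFFSETS
    dirs = np.stack([np.cos(bearings), np.sin(bearings)], axis=1)
    starts = ez.center[None, :] + (config.w_ex / 2.0) * dirs
    step = kin.dx * config.ray_step_frac
    gaps, runs = ray_runs(grid, starts, dirs, config.d_s + config.h_ex, step)
    return bearings, gaps, runs


def sense_wax(ez: ExcavationZone, grid: WaxGrid, config: SimulationConfig,
              kin: DerivedKinematics) -> float | None:
    """Bearing (absolute angle) of the nearest wax within ``d_s``, or None."""
    bearings, gaps, _ = _probe(ez, grid, config, kin)
    in_range = gaps <= config.d_s
    if not in_range.any():
        return None
    gaps = np.where(in_range, gaps, np.inf)
    return float(bearings[int(np.argmin(gaps))])


def front_thickness(ez: ExcavationZone, grid: WaxGrid, config: SimulationConfig,
                    kin: DerivedKinematics) -> float:
    """Thickness of the wax directly ahead, or inf when not in contact.

    The ray starts at the front tip (centre + r * heading) and is sampled
    up to ``h_ex``; contact means the gap is at most ``v_ex + step``.
    """
    step = kin.dx * config.ray_step_frac
    start = ez.center + (config.w_ex / 2.0) * _unit(ez.heading)
    gaps, runs = ray_runs(grid, start[None, :], _unit(ez.heading)[None, :],
                          config.h_ex, step)
    if gaps[0] <= kin.v_ex + step:
        return float(runs[0])
    return math.inf


def _admissible(gaps: np.ndarray, runs: np.ndarray, d_w: float) -> bool:
    """A pose is admissible if every probe touching wax sees run >= d_w."""
    touching = gaps <= 0.0
    return bool(np.all(runs[touching] >= d_w))


def rotation_admissible(ez: ExcavationZone, dtheta: float, grid: WaxGrid,
                        config: SimulationConfig, kin: DerivedKinematics) -> bool:
    """Whether rotating by ``dtheta`` would nowhere excavate sub-``d_w`` wax.

    The check casts the probe rays at the tentative heading: any ray in
    contact (gap 0) must see a wall at least ``d_w`` thick.
    """
    _, gaps, runs = _probe(ez, grid, config, kin, heading=ez.heading + dtheta)
    return _admissible(gaps, runs, config.d_w)


def _cells_to_remove(ez: ExcavationZone, grid: WaxGrid,
                     config: SimulationConfig, kin: DerivedKinematics):
    """On-cells inside the footprint at the (new) pose, as (ii, jj) arrays."""
    head, body = footprint_parts(ez, config, kin)
    cells = np.concatenate([head, body], axis=0)
    if cells.size == 0:
        return cells[:, :1].reshape(0), cells[:, :1].reshape(0)
    ii, jj = cells[:, 0], cells[:, 1]
    on = grid.occupancy[jj, ii]
    return ii[on], jj[on]


def behave(ez: ExcavationZone, grid: WaxGrid, rng: np.random.Generator,
           config: SimulationConfig, kin: DerivedKinematics):
    """One time-unit of the EZ behaviour policy.

    Returns ``(new_ez, (ii, jj))`` where ``(ii, jj)`` index the on-cells
    the move excavates (cells of the new footprint; the caller switches
    them off).  Collision handling between EZs is the engine's job.
    """
    step = kin.dx * config.ray_step_frac
    contact_dist = kin.v_ex + step
    bearings, gaps, runs = _probe(ez, grid, config, kin)
    contact = gaps <= contact_dist
    # The antenna band spans the whole front arc: wax at the thinness
    # limit anywhere across the front forbids forward motion, not just on
    # the axis — otherwise the flanks of the advancing semicircle could
    # slice through a wall the centre ray never saw.
    at_thin_wax = bool(np.any(contact & (runs < config.d_w)))

    def finish(center, heading, state):
        new = replace(ez, center=np.mod(center, (grid.lx, grid.ly)),
                      heading=heading % (2 * math.pi), state=state)
        return new, _cells_to_remove(new, grid, config, kin)

    if at_thin_wax:
        # Wax ahead is at the thinness limit: refuse to advance and rotate
        # to find a region thicker than d_w.  A direction is only worth
        # taking if the rotation is admissible *and* it actually offers
        # diggable (>= d_w) wax; if neither side does, the EZ is
        # surrounded by thin wax and halts in place.
        options = []
        for sgn in (1.0, -1.0):
            b2, g2, r2 = _probe(ez, grid, config, kin,
                                heading=ez.heading + sgn * kin.omega_ex)
            if not _admissible(g2, r2, config.d_w):
                continue
            sensed = g2 <= config.d_s
            score = float(r2[sensed].max()) if sensed.any() else 0.0
            if score >= config.d_w:
                options.append((sgn, score))
        if not options:
            return finish(ez.center, ez.heading, EZState.EQUILIBRIUM)
        best = max(score for _, score in options)
        tied = [sgn for sgn, score in options if score == best]
        sgn = tied[0] if len(tied) == 1 else tied[int(rng.integers(len(tied)))]
        return finish(ez.center, ez.heading + sgn * kin.omega_ex, EZState.ENGAGED)

    if contact[_FRONT]:
        # In frontal contact with wax thick enough everywhere: dig forward.
        return finish(ez.center + kin.v_ex * _unit(ez.heading), ez.heading,
                      EZState.ENGAGED)

    sensed = gaps <= config.d_s
    if not sensed.any():
        # Far from any wax: linear uniform motion.
        return finish(ez.center + kin.v_ex * _unit(ez.heading), ez.heading,
                      EZState.FREE)

    # Wax sensed within d_s but no frontal contact: approach by rotating
    # toward the nearest sensed bearing, then advance if still clear.
    bearing = float(bearings[int(np.argmin(np.where(sensed, gaps, np.inf)))])
    err = _wrap_angle(bearing - ez.heading)
    dtheta = max(-kin.omega_ex, min(kin.omega_ex, err))
    new_heading = ez.heading
    g3 = gaps
    if abs(dtheta) > 1e-12:
        _, g_rot, r_rot = _probe(ez, grid, config, kin,
                                 heading=ez.heading + dtheta)
        if _admissible(g_rot, r_rot, config.d_w):
            new_heading = ez.heading + dtheta
            g3 = g_rot
    center = ez.center
    if np.all(g3 > contact_dist):
        center = ez.center + kin.v_ex * _unit(new_heading)
    if new_heading == ez.heading and center is ez.center:
        # Can neither rotate nor advance: surrounded by thin wax.
        return finish(ez.center, ez.heading, EZState.EQUILIBRIUM)
    return finish(center, new_heading, EZState.APPROACH)
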