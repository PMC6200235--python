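"""Binary wax lattice and anisotropic Eden growth.

The wax cluster lives on an ``N_x`` x ``N_y`` lattice of binary cells.
Cell ``(i, j)`` (0-based, ``i`` along x, ``j`` along y) covers the
half-open box ``[i*dx, (i+1)*dx) x [j*dy, (j+1)*dy)``.  The occupancy
array is indexed ``occupancy[j, i]`` (row = y, column = x).

Growth follows the Eden rule: every off-cell 4-adjacent to an on-cell is
a candidate, and one candidate is switched on per time unit.  Anisotropy
is introduced class-first: with probability ``p_x`` the new cell is drawn
uniformly from the candidates that have an on-neighbour along x, else
from those with an on-neighbour along y (falling back to the other class
when the chosen one is empty).  Growth adjacency is *not* periodic — the
cluster stops at the lattice edge — whereas ray sampling and footprint
rasterisation elsewhere in the package wrap, matching the periodic
boundary of the excavation-zone motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig, derive_kinematics

__all__ = [
    "WaxGrid",
    "make_seeded_grid",
    "growth_candidates",
    "grow_one",
    "wax_count",
    "run_length",
    "ray_runs",
]


@dataclass
class WaxGrid:
    """Binary occupancy lattice with cell geometry.

    ``_bounds`` is a conservative (never shrinking) bounding box of all
    cells that have ever been on, used to restrict candidate searches.
    """

    occupancy: np.ndarray  # bool, shape (N_y, N_x), indexed [j, i]
    dx: float
    dy: float
    _bounds: list[int] | None = field(default=None, repr=False)  # [i0, i1, j0, j1]

    @property
    def nx(self) -> int:
        return self.occupancy.shape[1]

    @property
    def ny(self) -> int:
        return self.occupancy.shape[0]

    @property
    def lx(self) -> float:
        return self.nx * self.dx

    @property
    def ly(self) -> float:
        return self.ny * self.dy

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self._bounds is None and self.occupancy.any():
            js, is_ = np.nonzero(self.occupancy)
            self._bounds = [int(is_.min()), int(is_.max()), int(js.min()), int(js.max())]

    def set_on(self, i: int, j: int) -> None:
        self.occupancy[j, i] = True
        if self._bounds is None:
            self._bounds = [i, i, j, j]
        else:
            b = self._bounds
            b[0] = min(b[0], i)
            b[1] = max(b[1], i)
            b[2] = min(b[2], j)
            b[3] = max(b[3], j)

    def set_off(self, ii: np.ndarray, jj: np.ndarray) -> int:
        """Switch off the given cells; returns how many were on."""
        on = self.occupancy[jj, ii]
        self.occupancy[jj[on], ii[on]] = False
        return int(on.sum())

    def copy(self) -> "WaxGrid":
        return WaxGrid(self.occupancy.copy(), self.dx, self.dy,
                       None if self._bounds is None else list(self._bounds))


def make_seeded_grid(config: SimulationConfig) -> WaxGrid:
    """Grid with a centred ``(2k+1) x (2k+1)`` block of wax (k = seed_wax_cells)."""
    kin = derive_kinematics(config)
    side = 2 * config.seed_wax_cells + 1
    if side > min(config.N_x, config.N_y):
        raise ValueError(f"seed block {side}x{side} larger than "
                         f"{config.N_x}x{config.N_y} lattice")
    occ = np.zeros((config.N_y, config.N_x), dtype=bool)
    ci = config.N_x // 2
    cj = config.N_y // 2
    k = config.seed_wax_cells
    occ[cj - k:cj + k + 1, ci - k:ci + k + 1] = True
    return WaxGrid(occ, kin.dx, kin.dy)


def wax_count(grid: WaxGrid) -> int:
    """Number of on-cells."""
    return int(grid.occupancy.sum())


def _candidate_classes(grid: WaxGrid, excluded_mask: np.ndarray | None):
    """Flat indices (into the full lattice) of x- and y-class candidates.

    Restricted to the conservative cluster bounding box (+1 cell margin)
    for speed; correctness is unaffected because no candidate can lie
    further out.
    """
    if grid._bounds is None or not grid.occupancy.any():
        empty = np.empty(0, dtype=np.intp)
        return empty, empty
    i0, i1, j0, j1 = grid._bounds
    i0 = max(i0 - 1, 0)
    j0 = max(j0 - 1, 0)
    i1 = min(i1 + 1, grid.nx - 1)
    j1 = min(j1 + 1, grid.ny - 1)
    occ = grid.occupancy[j0:j1 + 1, i0:i1 + 1]
    off = ~occ
    xn = np.zeros_like(occ)
    xn[:, 1:] |= occ[:, :-1]
    xn[:, :-1] |= occ[:, 1:]
    yn = np.zeros_like(occ)
    yn[1:, :] |= occ[:-1, :]
    yn[:-1, :] |= occ[1:, :]
    if excluded_mask is not None:
        off = off & ~excluded_mask[j0:j1 + 1, i0:i1 + 1]
    xc = off & xn
    yc = off & yn
    jx, ix = np.nonzero(xc)
    jy, iy = np.nonzero(yc)
    x_flat = (jx + j0) * grid.nx + (ix + i0)
    y_flat = (jy + j0) * grid.nx + (iy + i0)
    return x_flat, y_flat


def growth_candidates(grid: WaxGrid, excluded: set[tuple[int, int]] | None = None):
    """All Eden growth candidates, tagged with their growth axis.

    Returns a list of ``((i, j), axis)`` pairs where ``axis`` is ``"x"``
    or ``"y"``; a cell with on-neighbours along both axes appears twice,
    once per class.  ``excluded`` is a set of ``(i, j)`` cells (typically
    the union of all EZ footprints) that may not receive wax.
    """
    mask = None
    if excluded:
        mask = np.zeros_like(grid.occupancy)
        for (i, j) in excluded:
            mask[j, i] = True
    x_flat, y_flat = _candidate_classes(grid, mask)
    out = [((int(f % grid.nx), int(f // grid.nx)), "x") for f in x_flat]
    out += [((int(f % grid.nx), int(f // grid.nx)), "y") for f in y_flat]
    return out


def grow_one(grid: WaxGrid, p_x: float, rng: np.random.Generator,
             excluded_mask: np.ndarray | None = None) -> tuple[int, int] | None:
    """Perform one Eden growth event; returns the cell turned on, or None.

    With probability ``p_x`` the x class is drawn from, else the y class;
    if the chosen class is empty the other is used; if both are empty the
    grid is unchanged and None is returned.
    """
    x_flat, y_flat = _candidate_classes(grid, excluded_mask)
    pick_x = rng.random() < p_x
    chosen = x_flat if pick_x else y_flat
    if chosen.size == 0:
        chosen = y_flat if pick_x else x_flat
    if chosen.size == 0:
        return None
    f = int(chosen[rng.integers(chosen.size)])
    i, j = f % grid.nx, f // grid.nx
    grid.set_on(i, j)
    return (i, j)


try:
    from numba import njit

    @njit(cache=True)
    def _ray_kernel(occ, starts, dirs, n, step, dx, dy):  # pragma: no cover
        k = starts.shape[0]
        ny, nx = occ.shape
        gaps = np.full(k, np.inf)
        runs = np.zeros(k)
        for r in range(k):
            sx, sy = starts[r, 0], starts[r, 1]
            ux, uy = dirs[r, 0], dirs[r, 1]
            cnt = 0
            for m in range(n):
                t = m * step
                ix = int(np.floor((sx + t * ux) / dx)) % nx
                iy = int(np.floor((sy + t * uy) / dy)) % ny
                if occ[iy, ix]:
                    if cnt == 0:
                        gaps[r] = t
                    cnt += 1
                elif cnt > 0:
                    break
            runs[r] = cnt * step
        return gaps, runs

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _ray_runs_numpy(occ, starts, dirs, n, step, dx, dy, nx, ny):
    ts = np.arange(n) * step
    pts = starts[:, None, :] + ts[None, :, None] * dirs[:, None, :]
    ix = np.floor(pts[..., 0] / dx).astype(np.intp) % nx
    iy = np.floor(pts[..., 1] / dy).astype(np.intp) % ny
    hit = occ[iy, ix]  # (k, n)
    k = starts.shape[0]
    gaps = np.full(k, np.inf)
    runs = np.zeros(k)
    for r in np.nonzero(hit.any(axis=1))[0]:
        row = hit[r]
        first = int(row.argmax())
        gaps[r] = ts[first]
        rest = ~row[first:]
        run_n = int(rest.argmax()) if rest.any() else row.size - first
        runs[r] = run_n * step
    return gaps, runs


def ray_runs(grid: WaxGrid, starts: np.ndarray, dirs: np.ndarray,
             max_dist: float, step: float | None = None):
    """Sample several rays against the lattice (periodic wrap).

    Parameters
    ----------
    starts, dirs : (k, 2) arrays
        Ray origins and unit directions in length units.
    max_dist : float
        Sampling horizon.
    step : float, optional
        Sampling interval; defaults to ``dx / 4``.

    Returns
    -------
    gaps, runs : (k,) arrays
        ``gaps[r]`` is the distance to the first on sample of ray ``r``
        (``inf`` if none within the horizon) and ``runs[r]`` the length of
        the contiguous on-run starting there (``n_on_samples * step``,
        truncated at the horizon).
    """
    if step is None:
        step = grid.dx / 4.0
    n = int(math.floor(max_dist / step)) + 1
    starts = np.ascontiguousarray(starts, dtype=np.float64)
    dirs = np.ascontiguousarray(dirs, dtype=np.float64)
    if _HAVE_NUMBA:
        return _ray_kernel(grid.occupancy, starts, dirs, n, step,
                           grid.dx, grid.dy)
    return _ray_runs_numpy(grid.occupancy, starts, dirs, n, step,
                           grid.dx, grid.dy, grid.nx, grid.ny)


def run_length(grid: WaxGrid, start, direction, max_dist: float,
               step: float | None = None) -> tuple[float, float]:
    """Gap to the first wax cell along a ray, and the on-run length there.

    ``gap`` is ``inf`` (and ``run`` 0) when no wax lies within
    ``max_dist``; ``gap`` is 0 when ``start`` itself is inside wax.
    """
    start = np.asarray(start, dtype=float)
    direction = np.asarray(direction, dtype=float)
    nrm = float(np.hypot(*direction))
    if not math.isclose(nrm, 1.0, rel_tol=1e-9):
        direction = direction / nrm
    gaps, runs = ray_runs(grid, start[None, :], direction[None, :], max_dist, step)
    return float(gaps[0]), float(runs[0])
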