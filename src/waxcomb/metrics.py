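"""Pattern metrics: wax-amount series, tripod and 1D-connection detectors.

The detectors quantify what the underlying model only shows visually:

* ``tripod_emerged`` — at least three non-moving (engaged or halted) EZs
  pressed against the main wax cluster, spread at least ``pi/2`` apart in
  bearing around its centroid.  This is the configuration in which three
  excavators carve the three-armed junction.
* ``branch_points`` — junctions of the morphological skeleton of the
  cluster (skeleton pixels with >= 3 skeleton neighbours, merged within
  a distance ``d_w``).
* ``aspect_ratio`` — x-extent over y-extent of the main cluster's
  bounding box; anisotropic growth elongates the cluster along x.

A cluster is called 1D-connected when it has at least two skeleton
branch points *and* an aspect ratio of at least 2 — the morphology of a
linear chain of tripods.  All thresholds are explicit keyword defaults;
none of them comes from the underlying behavioural model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize

from .config import DerivedKinematics, SimulationConfig
from .excavator import EZState, ExcavationZone, footprint_parts
from .grid import WaxGrid

__all__ = [
    "MetricsRecord",
    "tripod_emerged",
    "branch_points",
    "aspect_ratio",
    "cluster_extents",
    "first_detection_time",
    "one_d_connected",
    "windowed_growth_rate",
]

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity

COLUMNS = ("t", "wax_count", "n_free", "n_approach", "n_engaged",
           "n_equilibrium", "cells_removed_this_step", "tripod_flag",
           "branch_point_count", "aspect_ratio", "x_extent")


@dataclass
class MetricsRecord:
    """Per-step simulation metrics (one row per time unit, including t=0)."""

    rows: dict[str, list] = field(default_factory=lambda: {c: [] for c in COLUMNS})

    def append(self, **kwargs) -> None:
        missing = set(COLUMNS) - set(kwargs)
        if missing:
            raise ValueError(f"missing metric columns: {sorted(missing)}")
        for c in COLUMNS:
            self.rows[c].append(kwargs[c])

    def __len__(self) -> int:
        return len(self.rows["t"])

    def column(self, name: str) -> np.ndarray:
        if name not in self.rows:
            raise KeyError(f"unknown metrics column {name!r}")
        return np.asarray(self.rows[name])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({c: self.rows[c] for c in COLUMNS})

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _disk(radius_cells: int) -> np.ndarray:
    if radius_cells <= 0:
        return np.ones((1, 1), dtype=bool)
    r = radius_cells
    y, x = np.ogrid[-r:r + 1, -r:r + 1]
    return x * x + y * y <= r * r


def _main_cluster(grid: WaxGrid) -> np.ndarray | None:
    """Mask of the largest 4-connected on-component, or None if empty."""
    if not grid.occupancy.any():
        return None
    labels, n = ndimage.label(grid.occupancy, structure=_CROSS)
    if n == 1:
        return grid.occupancy
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(sizes)) + 1)


def tripod_emerged(grid: WaxGrid, ezs: list[ExcavationZone],
                   config: SimulationConfig, kin: DerivedKinematics,
                   min_separation: float = math.pi / 2) -> bool:
    """Whether a tripod-forming EZ configuration surrounds the cluster.

    True iff at least three EZs that are ENGAGED or in EQUILIBRIUM have
    footprints touching the main cluster dilated by ``d_s``, three of
    which sit at bearings (about the cluster centroid) pairwise separated
    by at least ``min_separation``.
    """
    mask = _main_cluster(grid)
    if mask is None:
        return False
    rad = max(1, math.ceil(config.d_s / kin.dx))
    near = ndimage.binary_dilation(mask, structure=_disk(rad))
    angles = []
    jj, ii = np.nonzero(mask)
    centroid = np.array([(ii.mean() + 0.5) * kin.dx, (jj.mean() + 0.5) * kin.dy])
    for ez in ezs:
        if ez.state not in (EZState.ENGAGED, EZState.EQUILIBRIUM):
            continue
        head, body = footprint_parts(ez, config, kin)
        cells = np.concatenate([head, body], axis=0)
        if cells.size == 0 or not near[cells[:, 1], cells[:, 0]].any():
            continue
        d = ez.center - centroid
        d -= np.array([grid.lx, grid.ly]) * np.round(d / (grid.lx, grid.ly))
        angles.append(math.atan2(d[1], d[0]))
    if len(angles) < 3:
        return False
    for trio in itertools.combinations(angles, 3):
        ok = all(
            min(abs(a - b) % (2 * math.pi), 2 * math.pi - abs(a - b) % (2 * math.pi))
            >= min_separation
            for a, b in itertools.combinations(trio, 2))
        if ok:
            return True
    return False


def branch_points(grid: WaxGrid, merge_dist: float | None = None) -> int:
    """Number of skeleton junctions of the wax cluster.

    The cluster is thinned to its morphological skeleton; pixels with at
    least three skeleton neighbours (8-connectivity) are branch pixels,
    and branch pixels within ``merge_dist`` of each other (default two
    cells, the minimum wax thickness at canonical parameters) count as a
    single junction.
    """
    if merge_dist is None:
        merge_dist = 2 * grid.dx
    if not grid.occupancy.any():
        return 0
    skel = skeletonize(grid.occupancy)
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    nbrs = ndimage.convolve(skel.astype(int), kernel, mode="constant")
    branch = skel & (nbrs >= 3)
    if not branch.any():
        return 0
    rad = int(round(merge_dist / grid.dx / 2))
    merged = ndimage.binary_dilation(branch, structure=_disk(rad))
    _, n = ndimage.label(merged, structure=np.ones((3, 3), dtype=bool))
    return int(n)


def cluster_extents(grid: WaxGrid) -> tuple[float, float]:
    """Bounding-box (x, y) extents of the main cluster, in length units."""
    mask = _main_cluster(grid)
    if mask is None:
        raise ValueError("cluster extents undefined for an empty grid")
    jj, ii = np.nonzero(mask)
    return (float((ii.max() - ii.min() + 1) * grid.dx),
            float((jj.max() - jj.min() + 1) * grid.dy))


def aspect_ratio(grid: WaxGrid) -> float:
    """x-extent / y-extent of the main cluster's bounding box (length units)."""
    x_extent, y_extent = cluster_extents(grid)
    return x_extent / y_extent


def one_d_connected(record: MetricsRecord, min_branches: int = 2,
                    min_aspect: float = 2.0,
                    min_x_extent: float = 0.45) -> np.ndarray:
    """Boolean series: the cluster is an elongated branched (1D) chain.

    A row qualifies when the main cluster has at least ``min_branches``
    skeleton junctions, an aspect ratio of at least ``min_aspect``, and
    an x-extent of at least ``min_x_extent``.  The extent floor (default
    three excavation depths, 3 * h_ex at canonical parameters) rejects
    the transient fluctuations of a young cluster smaller than a chain of
    two tripod units, which can momentarily look elongated and branched
    at skeleton scale.
    """
    bp = record.column("branch_point_count")
    ar = record.column("aspect_ratio")
    xe = record.column("x_extent")
    with np.errstate(invalid="ignore"):
        return (bp >= min_branches) & (ar >= min_aspect) & (xe >= min_x_extent)


def first_detection_time(record: MetricsRecord, column: str,
                         threshold: float | None = None) -> int | None:
    """Index of the first row where the named flag (or threshold) holds."""
    vals = record.column(column)
    if threshold is None:
        hits = np.array([bool(v) and not (isinstance(v, float) and math.isnan(v))
                         for v in vals])
    else:
        with np.errstate(invalid="ignore"):
            hits = np.nan_to_num(vals.astype(float), nan=-math.inf) >= threshold
    idx = np.nonzero(hits)[0]
    return int(idx[0]) if idx.size else None


def windowed_growth_rate(record: MetricsRecord, window: int = 200) -> np.ndarray:
    """Discrete growth rate of the wax amount, slope per window of steps.

    Returns one slope per non-overlapping window (least-squares fit).
    """
    w = record.column("wax_count").astype(float)
    n = len(w) // window
    slopes = []
    for k in range(n):
        seg = w[k * window:(k + 1) * window]
        x = np.arange(seg.size)
        slopes.append(float(np.polyfit(x, seg, 1)[0]))
    return np.array(slopes)
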