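"""Crypt unwrapping and graph distances to Paneth cells.

A crypt is represented by a manually annotated axis (3-6 control points per
time point) through which a natural cubic spline is interpolated and
re-parameterized by arc length.  Each tracked cell position is projected to
its closest point on the spline, giving a coordinate pair: the distance p
along the axis (zero at the bottom-most cell of that time point) and the
angle theta around the axis relative to the viewing direction.  Theta is
computed as an arccos, so it lives in [0, pi] and carries no sign.

Cell-neighbour relations are built per time point by linking each cell to
its five closest cells within a 15-um radius (nuclei are about 10 um with
about five neighbours each); the link distance delta of a cell is the
number of graph edges to the nearest Paneth cell minus one, with a direct
neighbour at delta = 0, summarized over a cell's lifetime by the mode.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree

__all__ = [
    "AxisSpline",
    "UnwrappedCoordinate",
    "DegenerateAngleError",
    "MissingCellError",
    "unwrap_positions",
    "build_neighbor_graph",
    "paneth_distances",
    "paneth_edge_distance",
    "lifetime_delta_mode",
]

NEIGHBOR_RADIUS_UM = 15.0
MAX_NEIGHBORS = 5
DEFAULT_VIEW_AXIS = np.array([0.0, 0.0, -1.0])


class DegenerateAngleError(ValueError):
    """Cell lies exactly on the crypt axis: the angle is undefined."""


class MissingCellError(KeyError):
    """Cell absent from the neighbour graph at a requested time."""


@dataclass(frozen=True)
class UnwrappedCoordinate:
    p: float  # um along the axis, >= 0 at each time point
    theta: float  # radians in [0, pi]
    r: float  # raw arc-length coordinate before the per-time-point shift


class AxisSpline:
    """Arc-length-parameterized crypt axis, one curve per annotated frame.

    Control points are interpolated with a natural cubic spline (straight
    line for two points) and densely resampled (0.5 um steps) so that the
    curve can be evaluated by arc length r.
    """

    RESAMPLE_STEP_UM = 0.5

    def __init__(self, annotation: pd.DataFrame):
        self._curves: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for frame, grp in annotation.groupby("frame"):
            pts = grp.sort_values("point_index")[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
            if len(pts) < 2:
                raise ValueError(f"frame {frame}: need at least 2 axis control points")
            self._curves[int(frame)] = self._resample(pts)

    @staticmethod
    def _resample(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        if len(pts) == 2:
            dense_u = np.linspace(0.0, chord[-1], max(int(chord[-1] / 0.1), 2))
            dense = np.column_stack([np.interp(dense_u, chord, pts[:, k]) for k in range(3)])
        else:
            cs = CubicSpline(chord, pts, bc_type="natural")
            dense_u = np.linspace(0.0, chord[-1], max(int(chord[-1] / 0.1), 2))
            dense = cs(dense_u)
        arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))])
        # resample at uniform arc-length steps
        r_grid = np.arange(0.0, arc[-1] + AxisSpline.RESAMPLE_STEP_UM, AxisSpline.RESAMPLE_STEP_UM)
        r_grid = np.clip(r_grid, 0.0, arc[-1])
        xyz = np.column_stack([np.interp(r_grid, arc, dense[:, k]) for k in range(3)])
        return r_grid, xyz

    @property
    def frames(self) -> list[int]:
        return sorted(self._curves)

    def r_max(self, frame: int) -> float:
        return float(self._curves[frame][0][-1])

    def point_at(self, frame: int, r) -> np.ndarray:
        r_grid, xyz = self._curves[frame]
        r = np.clip(np.asarray(r, dtype=float), 0.0, r_grid[-1])
        return np.column_stack([np.interp(r, r_grid, xyz[:, k]) for k in range(3)]).squeeze()

    def project(self, frame: int, x: np.ndarray, grid_step: float = 1.0) -> float:
        """Arc-length coordinate minimizing the distance from ``x`` to the
        curve: coarse grid search (1 um) refined by bounded scalar
        minimization; ties broken toward smaller r."""
        r_grid, xyz = self._curves[frame]
        coarse = np.arange(0.0, r_grid[-1] + grid_step, grid_step)
        coarse = np.clip(coarse, 0.0, r_grid[-1])
        pts = self.point_at(frame, coarse)
        d2 = np.sum((np.atleast_2d(pts) - x) ** 2, axis=1)
        i = int(np.argmin(d2))  # argmin returns the first (smallest-r) minimum
        lo = coarse[max(i - 1, 0)]
        hi = coarse[min(i + 1, len(coarse) - 1)]
        if hi - lo < 1e-12:
            return float(coarse[i])
        res = minimize_scalar(
            lambda r: float(np.sum((self.point_at(frame, r) - x) ** 2)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-4},
        )
        return float(min(res.x, coarse[i], key=lambda r: (float(np.sum((self.point_at(frame, r) - x) ** 2)), r)))

    def project_many(self, frame: int, X: np.ndarray) -> np.ndarray:
        """Vectorized projection of many points: argmin over the dense
        0.5-um arc-length table refined by a parabolic step (sub-grid
        accuracy ~0.01 um for smooth curves)."""
        r_grid, xyz = self._curves[frame]
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = ((X[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=2)  # (n, m)
        i = d2.argmin(axis=1)
        m = len(r_grid)
        il = np.clip(i - 1, 0, m - 1)
        ir = np.clip(i + 1, 0, m - 1)
        y0, y1, y2 = d2[np.arange(len(X)), il], d2[np.arange(len(X)), i], d2[np.arange(len(X)), ir]
        denom = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / np.where(denom == 0, 1, denom), 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        step = r_grid[1] - r_grid[0] if m > 1 else 0.0
        r = r_grid[i] + shift * step
        # parabolic refinement is invalid at the boundary grid points
        r[i == 0] = r_grid[0] + np.clip(shift[i == 0], 0, 1) * step
        r[i == m - 1] = r_grid[m - 1] + np.clip(shift[i == m - 1], -1, 0) * step
        return np.clip(r, 0.0, r_grid[-1])


def unwrap_positions(
    cells: pd.DataFrame,
    spline: AxisSpline,
    frame: int,
    view_axis: np.ndarray = DEFAULT_VIEW_AXIS,
) -> dict[str, UnwrappedCoordinate]:
    """Unwrap all cells of one frame into (p, theta) coordinates.

    ``cells`` must have columns cell_id, x_um, y_um, z_um.  p is measured
    from the bottom-most cell of the frame (the smallest projected r), and
    theta = acos(u . v / |u||v|) with v the offset of the cell from its
    projection point.
    """
    u = np.asarray(view_axis, dtype=float)
    u = u / np.linalg.norm(u)
    ids = cells["cell_id"].astype(str).to_numpy()
    X = cells[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    rs = spline.project_many(frame, X)
    P = np.atleast_2d(spline.point_at(frame, rs))
    V = X - P
    r_min = rs.min()
    out = {}
    for cid, r, v in zip(ids, rs, V):
        nv = np.linalg.norm(v)
        if nv == 0.0:
            raise DegenerateAngleError(f"cell {cid} lies exactly on the crypt axis")
        cosang = float(np.clip(np.dot(u, v) / nv, -1.0, 1.0))
        out[cid] = UnwrappedCoordinate(p=float(r - r_min), theta=math.acos(cosang), r=float(r))
    return out


def build_neighbor_graph(cells: pd.DataFrame) -> nx.Graph:
    """Undirected neighbour graph of one frame.

    Each cell is linked to its (at most) five closest cells within 15 um;
    the directed 5-nearest-within-radius relation is symmetrized by union,
    so degrees above five are possible but each cell *contributes* at most
    five edges.
    """
    ids = cells["cell_id"].astype(str).to_numpy()
    xyz = cells[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    g = nx.Graph()
    g.add_nodes_from(ids)
    if len(ids) < 2:
        return g
    tree = cKDTree(xyz)
    k = min(MAX_NEIGHBORS + 1, len(ids))
    dist, idx = tree.query(xyz, k=k)
    for i in range(len(ids)):
        for d, j in zip(dist[i, 1:], idx[i, 1:]):
            if d <= NEIGHBOR_RADIUS_UM:
                g.add_edge(ids[i], ids[j])
    return g


def paneth_distances(graph: nx.Graph, paneth_ids) -> dict[str, int]:
    """Link distance delta to the nearest Paneth cell for every reachable
    node: edge count minus one (a Paneth neighbour is at delta = 0); Paneth
    cells themselves get delta = 0.  Unreachable cells are absent."""
    sources = [p for p in paneth_ids if p in graph]
    if not sources:
        return {}
    hop = nx.multi_source_dijkstra_path_length(graph, sources)
    out = {}
    for node, d in hop.items():
        out[node] = 0 if d == 0 else int(d) - 1
    return out


def paneth_edge_distance(
    cell_id: str,
    graphs: dict[int, nx.Graph],
    paneth_ids_by_frame: dict[int, list[str]],
    frames: list[int],
) -> int | None:
    """Lifetime link distance of one cell: the mode of its per-frame delta
    distribution over the given frames (ties toward the smaller delta);
    ``None`` if no Paneth cell is ever reachable."""
    deltas = []
    for fr in frames:
        g = graphs[fr]
        if cell_id not in g:
            raise MissingCellError(f"cell {cell_id} absent from neighbour graph at frame {fr}")
        d = paneth_distances(g, paneth_ids_by_frame.get(fr, [])).get(cell_id)
        if d is not None:
            deltas.append(d)
    return lifetime_delta_mode(deltas)


def lifetime_delta_mode(deltas) -> int | None:
    """Mode of a per-time delta sequence, ties broken toward smaller delta."""
    if not len(deltas):
        return None
    counts = Counter(deltas)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return int(best[0])
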