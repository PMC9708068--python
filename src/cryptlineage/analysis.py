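"""High-level crypt analysis: ties the track table, the lineage forest, the
unwrapped geometry and the pair statistics together.

These are the convenience entry points a user calls on one crypt's data:
last axis position per cell (the classifier's villus criterion), division
events with their axis positions, the mother's Paneth link distance at
division, and the division-pattern tallies stratified by that distance —
the measurements behind the position-resolved (alpha, phi) estimates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import geometry
from .geometry import AxisSpline
from .lineage import (
    ClassifierParams,
    DivisionPatternCounts,
    EndReason,
    LineageForest,
    PairRecord,
    State,
    classify_forest,
    extract_pairs,
    tally_pair_outcomes,
)
from .popstats import CountSeries

__all__ = [
    "last_axis_positions",
    "division_events",
    "mother_delta_at_division",
    "division_patterns_by_delta",
    "count_series_from_forest",
    "analyze_crypt",
]


def _frame_of(forest: LineageForest, t: float, tracks: pd.DataFrame) -> int:
    f = tracks.loc[(tracks["t_hr"] - t).abs().idxmin(), "frame"]
    return int(f)


def _cells_at_frame(tracks: pd.DataFrame, frame: int) -> pd.DataFrame:
    return tracks.loc[tracks["frame"] == frame, ["cell_id", "x_um", "y_um", "z_um"]]


def last_axis_positions(tracks: pd.DataFrame, axis: pd.DataFrame) -> dict[str, float]:
    """Axis position p (um) of every cell at its last recorded frame.

    Frames are unwrapped lazily: only frames on which some cell is last
    seen are projected onto the spline.
    """
    spline = AxisSpline(axis)
    last_frames = tracks.groupby("cell_id")["frame"].max()
    out: dict[str, float] = {}
    for frame in sorted(last_frames.unique()):
        cells = _cells_at_frame(tracks, int(frame))
        coords = geometry.unwrap_positions(cells, spline, int(frame))
        for cid in last_frames.index[last_frames == frame]:
            out[str(cid)] = coords[str(cid)].p
    return out


def division_events(forest: LineageForest, tracks: pd.DataFrame, axis: pd.DataFrame) -> pd.DataFrame:
    """One row per division: mother id, division time and the mother's axis
    position at its last recorded frame (columns mother, t_hr, p_um)."""
    spline = AxisSpline(axis)
    mothers = [c for c in forest.iter_cells() if c.end_reason is EndReason.DIVIDED]
    by_frame: dict[int, list] = {}
    last_frame = tracks.groupby("cell_id")["frame"].max()
    for m in mothers:
        by_frame.setdefault(int(last_frame[m.cell_id]), []).append(m)
    rows = []
    for frame, ms in sorted(by_frame.items()):
        coords = geometry.unwrap_positions(_cells_at_frame(tracks, frame), spline, frame)
        for m in ms:
            rows.append((m.cell_id, m.t_end, coords[m.cell_id].p))
    return pd.DataFrame(rows, columns=["mother", "t_hr", "p_um"])


def mother_delta_at_division(forest: LineageForest, tracks: pd.DataFrame) -> dict[str, int | None]:
    """Paneth link distance of each dividing mother at its division frame.

    The neighbour graph is rebuilt from the recorded positions of all
    cells present on the mother's last frame; delta is the edge count to
    the nearest Paneth cell minus one (None when unreachable).
    """
    paneth_ids = set(tracks.loc[tracks["is_paneth"] == 1, "cell_id"].astype(str))
    last_frame = tracks.groupby("cell_id")["frame"].max()
    mothers = [c.cell_id for c in forest.iter_cells() if c.end_reason is EndReason.DIVIDED]
    by_frame: dict[int, list[str]] = {}
    for m in mothers:
        by_frame.setdefault(int(last_frame[m]), []).append(m)
    out: dict[str, int | None] = {}
    for frame, ms in sorted(by_frame.items()):
        g = geometry.build_neighbor_graph(_cells_at_frame(tracks, frame))
        deltas = geometry.paneth_distances(g, paneth_ids)
        for m in ms:
            out[m] = deltas.get(m)
    return out


def division_patterns_by_delta(
    forest: LineageForest,
    tracks: pd.DataFrame,
    classification: pd.DataFrame,
    delta_boundary: int = 1,
) -> dict[str, DivisionPatternCounts]:
    """Sister-pair outcome tallies split by the mother's Paneth distance:
    ``near`` (delta <= delta_boundary), ``far`` (beyond, including
    unreachable).  Paneth mothers never occur (Paneth cells do not divide).
    """
    deltas = mother_delta_at_division(forest, tracks)
    pairs = extract_pairs(forest, "sister", classification)
    parent_of = {p.cell_a: forest.cells[p.cell_a].parent_id for p in pairs}
    near: list[PairRecord] = []
    far: list[PairRecord] = []
    for p in pairs:
        mother = parent_of[p.cell_a]
        d = deltas.get(mother)
        (near if d is not None and d <= delta_boundary else far).append(p)
    return {"near": tally_pair_outcomes(near), "far": tally_pair_outcomes(far)}


def count_series_from_forest(
    forest: LineageForest,
    classification: pd.DataFrame,
    times: np.ndarray | None = None,
) -> CountSeries:
    """Counts over time: cells alive and classified proliferating, and the
    cumulative number of cells born (roots count as born at their first
    observation)."""
    if times is None:
        times = np.arange(0.0, forest.experiment_end + 1e-9, 1.0)
    births = np.sort([c.t_birth for c in forest.iter_cells()])
    prolif_ids = set(classification.index[classification["state"] == State.PROLIFERATING])
    n_prolif = []
    for t in times:
        n = sum(
            1
            for c in forest.iter_cells()
            if c.cell_id in prolif_ids and c.t_birth <= t < c.t_end
        )
        n_prolif.append(n)
    n_born = np.searchsorted(births, times, side="right")
    return CountSeries(times=np.asarray(times, dtype=float), n_proliferating=np.array(n_prolif, dtype=float), n_total_born=n_born.astype(float))


def analyze_crypt(
    tracks: pd.DataFrame,
    axis: pd.DataFrame,
    params: ClassifierParams = ClassifierParams(),
    delta_boundary: int = 1,
) -> dict:
    """End-to-end single-crypt analysis.

    Builds the forest, classifies every cell (using last axis positions
    for the villus criterion), and returns the forest, classification,
    sister/cousin tallies and the near/far division-pattern split.
    """
    from .lineage import build_lineage_forest

    forest = build_lineage_forest(tracks)
    axis_pos = last_axis_positions(tracks, axis)
    classification = classify_forest(forest, axis_pos, params)
    sisters = extract_pairs(forest, "sister", classification)
    cousins = extract_pairs(forest, "cousin", classification)
    return {
        "forest": forest,
        "classification": classification,
        "axis_positions": axis_pos,
        "sister_pairs": sisters,
        "cousin_pairs": cousins,
        "sister_counts": tally_pair_outcomes(sisters),
        "cousin_counts": tally_pair_outcomes(cousins),
        "patterns_by_delta": division_patterns_by_delta(forest, tracks, classification, delta_boundary),
    }
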