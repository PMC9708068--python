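"""Lineage forests, proliferative-state classification and division-symmetry
statistics.

The substrate is a forest of rooted binary trees reconstructed from a cell
track table: each tracked cell is a node with a birth time, an end time and
an end reason (divided / died / lost from tracking / experiment end).  On
top of the forest this module implements

* the proliferative-state classifier — a cell is *proliferating* when its
  division was observed, *non-proliferating* when it was followed for at
  least 30 hr without dividing or ended up beyond 60 um along the
  crypt-villus axis (divisions essentially never occur there), *dead* when
  it was seen to die, and *undetermined* otherwise;

* sister and cousin pair extraction and the division-pattern tallies
  (both daughters proliferate / both stop / one of each, plus death
  categories);

* the symmetry fraction phi, the (alpha, phi) estimator that inverts the
  division-mode probabilities p_pp = (phi+alpha)/2, p_nn = (phi-alpha)/2,
  p_asym = 1-phi, and the sister cell-cycle correlation.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EndReason",
    "State",
    "CellRecord",
    "LineageForest",
    "ClassifierParams",
    "PairRecord",
    "DivisionPatternCounts",
    "MalformedTreeError",
    "UndefinedStatisticError",
    "build_lineage_forest",
    "classify_state",
    "classify_forest",
    "extract_pairs",
    "tally_pair_outcomes",
    "symmetry_fraction",
    "estimate_alpha_phi",
    "alpha_phi_standard_errors",
    "sister_cycle_correlation",
]


class MalformedTreeError(ValueError):
    """A parent without exactly 0 or 2 children, or inconsistent timing."""


class UndefinedStatisticError(ValueError):
    """A statistic requested on an empty or insufficient sample."""


class EndReason(str, Enum):
    DIVIDED = "divided"
    DIED = "died"
    LOST = "lost"
    EXPERIMENT_END = "experiment_end"


class State(str, Enum):
    PROLIFERATING = "proliferating"
    NON_PROLIFERATING = "non_proliferating"
    DEAD = "dead"
    UNDETERMINED = "undetermined"


@dataclass
class CellRecord:
    cell_id: str
    parent_id: str | None
    t_birth: float
    t_end: float
    end_reason: EndReason
    is_paneth: bool = False
    # time-ordered observations: arrays of equal length
    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    positions: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    @property
    def observed_duration(self) -> float:
        return self.t_end - self.t_birth

    @property
    def cycle_time(self) -> float | None:
        """Cell-cycle duration; defined only for cells whose division was seen."""
        if self.end_reason is EndReason.DIVIDED:
            return self.t_end - self.t_birth
        return None


@dataclass
class LineageForest:
    cells: dict[str, CellRecord]
    children: dict[str, list[str]]
    roots: list[str]
    experiment_end: float
    frame_interval: float

    def __len__(self) -> int:
        return len(self.cells)

    def parent_of(self, cell_id: str) -> str | None:
        return self.cells[cell_id].parent_id

    def children_of(self, cell_id: str) -> list[str]:
        return self.children.get(cell_id, [])

    def iter_cells(self) -> Iterable[CellRecord]:
        return self.cells.values()


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the proliferative-state classifier (hours / um)."""

    min_nondividing_obs: float = 30.0
    villus_cutoff: float = 60.0
    end_exclusion: float = 15.0
    assume_unclassified_nonproliferating: bool = False

    def __post_init__(self) -> None:
        if min(self.min_nondividing_obs, self.villus_cutoff, self.end_exclusion) <= 0:
            raise ValueError("classifier thresholds must be strictly positive")


def build_lineage_forest(tracks: pd.DataFrame, frame_interval: float | None = None) -> LineageForest:
    """Assemble a lineage forest from a track table (one row per cell per frame).

    End reasons are inferred: *divided* if the cell has children, *died* if
    its death flag is set, *experiment_end* if its last frame is the final
    frame of the table, *lost* otherwise.  A parent with one or more than
    two children raises :class:`MalformedTreeError`.
    """
    if len(tracks) == 0:
        raise ValueError("empty track table")
    t_by_frame = tracks.drop_duplicates("frame").set_index("frame")["t_hr"].sort_index()
    if frame_interval is None:
        frame_interval = float(np.diff(t_by_frame.values).min()) if len(t_by_frame) > 1 else 0.2
    final_frame = int(tracks["frame"].max())
    experiment_end = float(t_by_frame.loc[final_frame])

    children: dict[str, list[str]] = {}
    cells: dict[str, CellRecord] = {}
    for cell_id, grp in tracks.groupby("cell_id", sort=False):
        grp = grp.sort_values("frame")
        parent = grp["parent_id"].iloc[0]
        parent = None if (pd.isna(parent) or parent == "") else str(parent)
        times = grp["t_hr"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise MalformedTreeError(f"cell {cell_id}: observation times not strictly increasing")
        cells[str(cell_id)] = CellRecord(
            cell_id=str(cell_id),
            parent_id=parent,
            t_birth=float(times[0]),
            t_end=float(times[-1]),
            end_reason=EndReason.LOST,  # provisional
            is_paneth=bool(grp["is_paneth"].iloc[-1]),
            times=times,
            positions=grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
        )
        if parent is not None:
            children.setdefault(parent, []).append(str(cell_id))

    for parent, kids in children.items():
        if parent not in cells:
            raise MalformedTreeError(f"parent {parent} referenced but never tracked")
        if len(kids) != 2:
            raise MalformedTreeError(f"cell {parent} has {len(kids)} children; expected 0 or 2")

    for cell in cells.values():
        kids = children.get(cell.cell_id)
        died = bool(tracks.loc[tracks["cell_id"] == cell.cell_id, "died"].iloc[-1])
        if kids:
            cell.end_reason = EndReason.DIVIDED
            for kid in kids:
                gap = cells[kid].t_birth - cell.t_end
                if not (-1e-9 <= gap <= frame_interval + 1e-9):
                    raise MalformedTreeError(
                        f"cell {kid} born {gap:.3f} hr after parent {cell.cell_id} ended; "
                        f"expected within one frame interval ({frame_interval} hr)"
                    )
        elif died:
            cell.end_reason = EndReason.DIED
        elif cell.times[-1] >= t_by_frame.loc[final_frame] - 1e-9:
            cell.end_reason = EndReason.EXPERIMENT_END
        else:
            cell.end_reason = EndReason.LOST

    roots = [c.cell_id for c in cells.values() if c.parent_id is None]
    return LineageForest(
        cells=cells, children=children, roots=roots,
        experiment_end=experiment_end, frame_interval=frame_interval,
    )


def classify_state(
    cell: CellRecord,
    forest: LineageForest,
    axis_position: float | None,
    params: ClassifierParams = ClassifierParams(),
) -> State:
    """Proliferative state of one cell.  ``axis_position`` is the cell's last
    recorded distance along the crypt axis (um); pass ``None`` if unknown."""
    if cell.end_reason is EndReason.DIED:
        return State.DEAD
    if cell.end_reason is EndReason.DIVIDED:
        return State.PROLIFERATING
    if cell.observed_duration >= params.min_nondividing_obs:
        return State.NON_PROLIFERATING
    if axis_position is not None and axis_position > params.villus_cutoff:
        return State.NON_PROLIFERATING
    if params.assume_unclassified_nonproliferating:
        return State.NON_PROLIFERATING
    return State.UNDETERMINED


def is_excluded(cell: CellRecord, forest: LineageForest, params: ClassifierParams = ClassifierParams()) -> bool:
    """Cells born less than ``end_exclusion`` hours before the experiment end
    are flagged and left out of pair statistics."""
    return cell.t_birth > forest.experiment_end - params.end_exclusion


def classify_forest(
    forest: LineageForest,
    axis_positions: Mapping[str, float] | None = None,
    params: ClassifierParams = ClassifierParams(),
) -> pd.DataFrame:
    """Classify every cell; returns a DataFrame indexed by cell_id with
    columns ``state`` and ``excluded``."""
    axis_positions = axis_positions or {}
    rows = {}
    for cell in forest.iter_cells():
        state = classify_state(cell, forest, axis_positions.get(cell.cell_id), params)
        rows[cell.cell_id] = (state, is_excluded(cell, forest, params))
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["state", "excluded"])
    df.index.name = "cell_id"
    return df


@dataclass(frozen=True)
class PairRecord:
    kind: str  # "sister" or "cousin"
    cell_a: str
    cell_b: str
    state_a: State
    state_b: State
    cycle_a: float | None
    cycle_b: float | None
    excluded: bool = False


def extract_pairs(
    forest: LineageForest,
    kind: str,
    classification: pd.DataFrame | None = None,
    params: ClassifierParams = ClassifierParams(),
    axis_positions: Mapping[str, float] | None = None,
) -> list[PairRecord]:
    """All sister (resp. cousin) pairs of the forest, each unordered pair once.

    Sisters share a parent; cousins share a grandparent but not a parent.
    Any resolvable cousin pair is included (all four grandchildren need not
    be tracked).  Pairs containing an excluded cell are marked.
    """
    if kind not in ("sister", "cousin"):
        raise ValueError("kind must be 'sister' or 'cousin'")
    if classification is None:
        classification = classify_forest(forest, axis_positions, params)

    def make_pair(a: str, b: str) -> PairRecord:
        a, b = sorted((a, b))
        ca, cb = forest.cells[a], forest.cells[b]
        return PairRecord(
            kind=kind,
            cell_a=a,
            cell_b=b,
            state_a=classification.loc[a, "state"],
            state_b=classification.loc[b, "state"],
            cycle_a=ca.cycle_time,
            cycle_b=cb.cycle_time,
            excluded=bool(classification.loc[a, "excluded"] or classification.loc[b, "excluded"]),
        )

    pairs: list[PairRecord] = []
    if kind == "sister":
        for kids in forest.children.values():
            pairs.append(make_pair(kids[0], kids[1]))
    else:
        for kids in forest.children.values():  # kids are siblings (potential parents of cousins)
            left = forest.children_of(kids[0])
            right = forest.children_of(kids[1])
            for a in left:
                for b in right:
                    pairs.append(make_pair(a, b))
    return pairs


@dataclass
class DivisionPatternCounts:
    """Counts of sister/cousin pair outcomes.

    pp: both proliferate, nn: both stop, pn: one of each; death categories
    are kept separate (death impacts pairs asymmetrically in the data and
    is not part of the proliferate/stop balance).
    """

    n_pp: int = 0
    n_nn: int = 0
    n_pn: int = 0
    n_death_one: int = 0
    n_death_both: int = 0
    n_excluded: int = 0

    @property
    def n_classified(self) -> int:
        return self.n_pp + self.n_nn + self.n_pn

    @property
    def n_total(self) -> int:
        return self.n_classified + self.n_death_one + self.n_death_both + self.n_excluded

    def fractions(self, include_death: bool = False) -> dict[str, float]:
        """Category fractions.  With ``include_death`` the denominator is all
        non-excluded pairs (death categories included); without, only the
        pp/nn/pn pairs — both normalizations are meaningful and the caller
        picks one explicitly."""
        denom = self.n_classified + (self.n_death_one + self.n_death_both if include_death else 0)
        if denom == 0:
            raise UndefinedStatisticError("no classified pairs")
        out = {"pp": self.n_pp / denom, "nn": self.n_nn / denom, "pn": self.n_pn / denom}
        if include_death:
            out["death_one"] = self.n_death_one / denom
            out["death_both"] = self.n_death_both / denom
        return out

    def as_rows(self, include_death: bool = False):
        fr = self.fractions(include_death=include_death)
        counts = {
            "pp": self.n_pp, "nn": self.n_nn, "pn": self.n_pn,
            "death_one": self.n_death_one, "death_both": self.n_death_both,
        }
        return [(cat, counts[cat], fr[cat]) for cat in fr]


def tally_pair_outcomes(pairs: Sequence[PairRecord]) -> DivisionPatternCounts:
    """Partition pairs into division-pattern categories.

    Death dominates (a pair with a dead member goes to a death category);
    pairs with an undetermined or excluded member go to ``n_excluded``.
    """
    c = DivisionPatternCounts()
    for p in pairs:
        a, b = p.state_a, p.state_b
        if a is State.DEAD and b is State.DEAD:
            c.n_death_both += 1
        elif a is State.DEAD or b is State.DEAD:
            c.n_death_one += 1
        elif p.excluded or a is State.UNDETERMINED or b is State.UNDETERMINED:
            c.n_excluded += 1
        elif a is State.PROLIFERATING and b is State.PROLIFERATING:
            c.n_pp += 1
        elif a is State.NON_PROLIFERATING and b is State.NON_PROLIFERATING:
            c.n_nn += 1
        else:
            c.n_pn += 1
    return c


def symmetry_fraction(counts: DivisionPatternCounts) -> float:
    """Fraction of pairs with symmetric proliferative outcome,
    (pp + nn) / (pp + nn + pn), ignoring death pairs."""
    denom = counts.n_classified
    if denom == 0:
        raise UndefinedStatisticError("symmetry fraction undefined: no classified pairs")
    return (counts.n_pp + counts.n_nn) / denom


def estimate_alpha_phi(counts: DivisionPatternCounts) -> tuple[float, float]:
    """Invert the division-mode probabilities: with fractions f_pp, f_nn,
    f_pn of the classified pairs, phi = f_pp + f_nn and alpha = f_pp - f_nn."""
    fr = counts.fractions(include_death=False)
    return fr["pp"] - fr["nn"], fr["pp"] + fr["nn"]


def alpha_phi_standard_errors(counts: DivisionPatternCounts) -> tuple[float, float]:
    """Multinomial standard errors of the (alpha, phi) estimates."""
    n = counts.n_classified
    if n == 0:
        raise UndefinedStatisticError("no classified pairs")
    fr = counts.fractions(include_death=False)
    f_pp, f_nn = fr["pp"], fr["nn"]
    var_alpha = (f_pp + f_nn - (f_pp - f_nn) ** 2) / n
    var_phi = (f_pp + f_nn) * (1.0 - f_pp - f_nn) / n
    return math.sqrt(max(var_alpha, 0.0)), math.sqrt(max(var_phi, 0.0))


def sister_cycle_correlation(pairs: Sequence[PairRecord]) -> float:
    """Pearson correlation of sister cell-cycle durations.

    Each unordered pair enters symmetrically (both orderings), so the
    statistic does not depend on pair-member labels."""
    xs, ys = [], []
    for p in pairs:
        if p.cycle_a is not None and p.cycle_b is not None:
            xs.extend((p.cycle_a, p.cycle_b))
            ys.extend((p.cycle_b, p.cycle_a))
    if len(xs) < 4:
        raise UndefinedStatisticError("need at least 2 pairs with both cycle times known")
    return float(np.corrcoef(xs, ys)[0, 1])
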