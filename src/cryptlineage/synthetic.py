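"""Synthetic crypt-tracking data with exported ground truth.

The generator emulates the statistical structure of tracked organoid
crypts, not their mechanics: cells live on the surface of a cylinder of
radius 20 um whose axis lies along +x (the crypt-villus axis, horizontal
in the imaging frame so the unwrapping angle is informative), with a few
non-dividing Paneth cells fixed near the base.  Dividing mothers choose a
division mode from the position-dependent probabilities
(p_pp, p_nn, p_asym) = ((phi+alpha(delta))/2, (phi-alpha(delta))/2, 1-phi),
where delta is the mother's link distance to the nearest Paneth cell on
the 5-nearest-neighbour graph at the division frame (the same definition
the analysis uses).  Defaults follow the measured organoid values: about
30 proliferating cells, skew-normal cycles with mean 16.2 hr, sister
cycle-time correlation 0.8, alpha = +0.67 within one cell of a Paneth
cell and -0.67 beyond, phi = 0.98.  Non-proliferating cells drift
distally at constant speed; each division nudges every cell distal to the
mother by one cell-area's worth of axial displacement, giving the
conveyor-belt motion that clears arrested cells past the 60-um villus
boundary.  Deaths and track losses are injected independently per cell.

Frames are sampled every 0.2 hr (the 12-min acquisition interval) and
written in the standard track-table dialect, so every downstream stage
(forest building, classification, unwrapping, Paneth distances, pair and
clone statistics) can run on generated data without any real recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import geometry
from .models import CycleDistribution

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "generate_crypt_tracks",
    "truncate_experiment",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class GeneratorParams:
    n_paneth: int = 3
    crypt_radius: float = 20.0  # um
    duration: float = 60.0  # hr
    frame_interval: float = 0.2  # hr (12 min)
    alpha_near: float = 0.67  # proliferative bias for delta <= delta_boundary
    alpha_far: float = -0.67  # and beyond
    delta_boundary: int = 1
    phi: float = 0.98
    cycle_dist: CycleDistribution = field(default_factory=CycleDistribution.default)
    sister_cycle_corr: float = 0.8
    death_prob: float = 0.05  # per newborn cell
    loss_prob: float = 0.07  # per newborn cell (tracking loss)
    n_initial_proliferating: int = 30
    n_initial_nonproliferating: int = 12
    drift_speed: float = 1.5  # um/hr distal drift of non-proliferating cells
    push_per_division: float = 0.6  # um axial push of cells distal to a division
    position_jitter: float = 0.25  # um recording noise
    seed: int | None = None

    def __post_init__(self) -> None:
        for a in (self.alpha_near, self.alpha_far):
            if abs(a) > self.phi:
                raise ValueError(f"|alpha|={abs(a)} exceeds phi={self.phi}")
        for p in (self.death_prob, self.loss_prob, self.sister_cycle_corr):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def alpha_at(self, delta: int | None) -> float:
        if delta is None or delta > self.delta_boundary:
            return self.alpha_far
        return self.alpha_near


@dataclass
class GroundTruth:
    """What the generator knows: per-cell fate, per-division outcome, the
    generating parameters and end-of-experiment clone sizes."""

    states: dict[str, str]  # cell_id -> proliferating / non_proliferating / dead
    divisions: pd.DataFrame  # mother, daughter_1, daughter_2, t_hr, delta_mother, mode
    alpha_near: float
    alpha_far: float
    delta_boundary: int
    phi: float
    sister_cycle_corr: float
    clone_sizes: dict[str, int]  # root cell -> living descendants at the end


class _Cell:
    __slots__ = (
        "cid", "parent", "a", "psi", "prolif", "t_birth", "t_div",
        "t_death", "t_loss", "cycle", "frames", "died_flag", "fate",
    )

    def __init__(self, cid, parent, a, psi, prolif, t_birth, cycle, t_div, t_death, t_loss):
        self.cid = cid
        self.parent = parent
        self.a = a  # axial position, um
        self.psi = psi  # angle around the axis, rad
        self.prolif = prolif
        self.t_birth = t_birth
        self.cycle = cycle
        self.t_div = t_div
        self.t_death = t_death
        self.t_loss = t_loss
        self.frames = []  # rows: (frame, t, x, y, z)
        self.died_flag = False
        self.fate = "proliferating" if prolif else "non_proliferating"


def _xyz(a: float, psi: float, R: float) -> tuple[float, float, float]:
    # axis along +x; cells on the cylinder surface
    return a, R * math.sin(psi), R * math.cos(psi)


def _correlated_cycles(dist: CycleDistribution, rho: float, rng: np.random.Generator) -> tuple[float, float]:
    """Sister cycle times from a Gaussian copula with skew-normal marginals."""
    z0 = rng.standard_normal()
    e1, e2 = rng.standard_normal(2)
    s = math.sqrt(max(1.0 - rho, 0.0))
    z1 = math.sqrt(rho) * z0 + s * e1
    z2 = math.sqrt(rho) * z0 + s * e2
    u = stats.norm.cdf([z1, z2])
    c = dist.ppf(np.clip(u, 1e-12, 1 - 1e-12))
    return float(max(c[0], 0.1)), float(max(c[1], 0.1))


def _snap(t: float, dt: float) -> float:
    return round(t / dt) * dt


def generate_crypt_tracks(
    params: GeneratorParams = GeneratorParams(),
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one crypt; returns (track table, axis annotation, truth)."""
    if rng is None:
        rng = params.seed
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    dt = params.frame_interval
    n_frames = int(round(params.duration / dt)) + 1
    R = params.crypt_radius

    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"c{counter[0]:05d}"

    # Paneth cells: fixed near the crypt base, evenly spaced in angle
    paneth: list[_Cell] = []
    for k in range(params.n_paneth):
        c = _Cell(new_id(), None, 4.0 + rng.uniform(-1, 1), 2 * math.pi * k / params.n_paneth,
                  False, 0.0, None, math.inf, math.inf, math.inf)
        paneth.append(c)
    paneth_ids = {c.cid for c in paneth}

    cells: list[_Cell] = list(paneth)
    mean_cycle = params.cycle_dist.mean
    for _ in range(params.n_initial_proliferating):
        a = rng.uniform(6.0, 32.0)
        cyc = float(params.cycle_dist.sample(rng, 1)[0])
        age = rng.uniform(0.0, min(mean_cycle, cyc) * 0.95)
        t_div = max(_snap(cyc - age, dt), dt)
        cells.append(_Cell(new_id(), None, a, rng.uniform(0, 2 * math.pi), True, 0.0, cyc, t_div, math.inf, math.inf))
    for _ in range(params.n_initial_nonproliferating):
        a = rng.uniform(32.0, 75.0)
        cells.append(_Cell(new_id(), None, a, rng.uniform(0, 2 * math.pi), False, 0.0, None, math.inf, math.inf, math.inf))

    truth_divisions = []
    all_cells: dict[str, _Cell] = {c.cid: c for c in cells}
    children: dict[str, list[str]] = {}

    def schedule_daughter(parent: _Cell, prolif: bool, cycle: float, t_now: float, dpsi: float, da: float) -> _Cell:
        t_death = math.inf
        t_loss = math.inf
        if rng.random() < params.death_prob:
            t_death = _snap(t_now + rng.uniform(2.0, 14.0), dt)
        if rng.random() < params.loss_prob:
            t_loss = _snap(t_now + rng.uniform(1.0, 25.0), dt)
        t_div = math.inf
        if prolif and t_death == math.inf:
            t_div = max(_snap(t_now + cycle, dt), t_now + dt)
        c = _Cell(new_id(), parent.cid, parent.a + da, parent.psi + dpsi, prolif,
                  t_now, cycle if prolif else None, t_div, t_death, t_loss)
        if t_death < math.inf:
            c.fate = "dead"
        return c

    def frame_table(live: list[_Cell]):
        return pd.DataFrame(
            {
                "cell_id": [c.cid for c in live],
                "x_um": [_xyz(c.a, c.psi, R)[0] for c in live],
                "y_um": [_xyz(c.a, c.psi, R)[1] for c in live],
                "z_um": [_xyz(c.a, c.psi, R)[2] for c in live],
            }
        )

    live: list[_Cell] = list(cells)
    eps = 1e-9
    for fi in range(n_frames):
        t = fi * dt
        # record positions
        for c in live:
            x, y, z = _xyz(c.a, c.psi, R)
            jx, jy, jz = rng.normal(0.0, params.position_jitter, 3)
            c.frames.append((fi, round(t, 6), x + jx, y + jy, z + jz))

        if fi == n_frames - 1:
            break

        # deaths and losses take effect after their last recorded frame
        next_live = []
        for c in live:
            if c.t_death <= t + eps:
                c.died_flag = True
            elif c.t_loss <= t + eps:
                pass  # track simply ends
            else:
                next_live.append(c)
        live = next_live

        # divisions due at this frame
        dividers = [c for c in live if c.prolif and c.t_div <= t + eps]
        if dividers:
            g = geometry.build_neighbor_graph(frame_table(live))
            deltas = geometry.paneth_distances(g, paneth_ids)
        for mother in dividers:
            live.remove(mother)
            delta_m = deltas.get(mother.cid)
            alpha = params.alpha_at(delta_m)
            u = rng.random()
            p_pp = (params.phi + alpha) / 2.0
            p_nn = (params.phi - alpha) / 2.0
            if u < p_pp:
                fates, mode = (True, True), "both_proliferate"
            elif u < p_pp + p_nn:
                fates, mode = (False, False), "both_stop"
            else:
                fates = (True, False) if rng.random() < 0.5 else (False, True)
                mode = "asymmetric"
            c1, c2 = _correlated_cycles(params.cycle_dist, params.sister_cycle_corr, rng)
            dpsi = 5.0 / R  # ~5 um arc separation
            d1 = schedule_daughter(mother, fates[0], c1, t + dt, +dpsi / 2, rng.normal(+1.0, 0.5))
            d2 = schedule_daughter(mother, fates[1], c2, t + dt, -dpsi / 2, rng.normal(-1.0, 0.5))
            for d in (d1, d2):
                all_cells[d.cid] = d
            children[mother.cid] = [d1.cid, d2.cid]
            truth_divisions.append(
                {
                    "mother": mother.cid, "daughter_1": d1.cid, "daughter_2": d2.cid,
                    "t_hr": round(t + dt, 6),
                    "delta_mother": -1 if delta_m is None else delta_m,
                    "mode": mode,
                }
            )
            # crowding: cells distal to the mother shift by one cell-area
            for c in live:
                if c.a > mother.a:
                    c.a += params.push_per_division
            live.extend((d1, d2))

        # passive motion
        for c in live:
            if c.cid in paneth_ids:
                continue
            if not c.prolif:
                c.a += params.drift_speed * dt
            c.a += rng.normal(0.0, 0.08)
            c.a = max(c.a, 1.0)
            c.psi += rng.normal(0.0, 0.01)

    # assemble the track table
    rows = []
    for c in all_cells.values():
        if not c.frames:
            continue
        last = len(c.frames) - 1
        for i, (fi, t, x, y, z) in enumerate(c.frames):
            rows.append(
                (
                    c.cid, c.parent if c.parent is not None else "",
                    fi, t, round(x, 3), round(y, 3), round(z, 3),
                    int(c.cid in paneth_ids), int(c.died_flag and i == last),
                )
            )
    tracks = pd.DataFrame(rows, columns=["cell_id", "parent_id", "frame", "t_hr", "x_um", "y_um", "z_um", "is_paneth", "died"])
    tracks = tracks.sort_values(["frame", "cell_id"], kind="stable").reset_index(drop=True)

    # axis annotation: a straight axis along x, re-emitted per frame
    ax_rows = []
    for fi in range(n_frames):
        for k, ax in enumerate((0.0, 40.0, 80.0, 120.0)):
            ax_rows.append((fi, k, ax, 0.0, 0.0))
    axis = pd.DataFrame(ax_rows, columns=["frame", "point_index", "x_um", "y_um", "z_um"])

    # ground truth
    states = {}
    for c in all_cells.values():
        if c.cid in paneth_ids:
            states[c.cid] = "non_proliferating"
        elif c.fate == "dead":
            states[c.cid] = "dead"
        else:
            states[c.cid] = "proliferating" if c.prolif else "non_proliferating"

    def living_descendants(cid: str) -> int:
        c = all_cells[cid]
        if cid in children:
            return sum(living_descendants(k) for k in children[cid])
        if c.died_flag:
            return 0
        return 1

    clone_sizes = {c.cid: living_descendants(c.cid) for c in cells if c.cid not in paneth_ids}

    truth = GroundTruth(
        states=states,
        divisions=pd.DataFrame(truth_divisions) if truth_divisions else pd.DataFrame(
            columns=["mother", "daughter_1", "daughter_2", "t_hr", "delta_mother", "mode"]
        ),
        alpha_near=params.alpha_near,
        alpha_far=params.alpha_far,
        delta_boundary=params.delta_boundary,
        phi=params.phi,
        sister_cycle_corr=params.sister_cycle_corr,
        clone_sizes=clone_sizes,
    )
    return tracks, axis, truth


def truncate_experiment(tracks: pd.DataFrame, new_duration: float) -> pd.DataFrame:
    """Drop all rows recorded after ``new_duration`` hours.

    Cells whose death or later divisions fall beyond the cut lose those
    events (the death flag lives on the dropped rows; daughters born after
    the cut vanish entirely), so end reasons recomputed on the truncated
    table mark cells alive at the cut as *experiment_end*.
    """
    out = tracks[tracks["t_hr"] <= new_duration + 1e-9].reset_index(drop=True).copy()
    # a parent whose own rows were all cut must not dangle
    kept = set(out["cell_id"])
    missing_parent = (out["parent_id"] != "") & ~out["parent_id"].isin(kept)
    out.loc[missing_parent, "parent_id"] = ""
    return out


def make_fixture_suite(seed: int = 0) -> dict[str, dict]:
    """Small deterministic datasets used across the test suite.

    ``seven_cell`` is a hand-checkable complete two-division forest
    (1 root -> 2 daughters -> 4 granddaughters: 3 sister pairs, 4 cousin
    pairs); the others are generated crypts exercising one feature each.
    """
    suite: dict[str, dict] = {}
    suite["seven_cell"] = {"tracks": _seven_cell_tracks(), "axis": _straight_axis(n_frames=101), "truth": None}

    base = GeneratorParams(duration=45.0, n_initial_proliferating=12, n_initial_nonproliferating=6)
    variants = {
        "phi_one": replace(base, phi=1.0, alpha_near=0.8, alpha_far=-0.8, death_prob=0.0, loss_prob=0.0),
        "phi_zero": replace(base, phi=0.0, alpha_near=0.0, alpha_far=0.0, death_prob=0.0, loss_prob=0.0),
        "dying": replace(base, death_prob=0.35),
        "censored": replace(base, loss_prob=0.35),
    }
    for i, (name, p) in enumerate(variants.items()):
        tracks, axis, truth = generate_crypt_tracks(p, rng=np.random.default_rng(seed * 7919 + i))
        suite[name] = {"tracks": tracks, "axis": axis, "truth": truth}
    return suite


def _straight_axis(n_frames: int) -> pd.DataFrame:
    rows = [(fi, k, ax, 0.0, 0.0) for fi in range(n_frames) for k, ax in enumerate((0.0, 50.0, 100.0))]
    return pd.DataFrame(rows, columns=["frame", "point_index", "x_um", "y_um", "z_um"])


def _seven_cell_tracks() -> pd.DataFrame:
    """Root m divides at 10 hr into s1, s2; each divides at 26 hr into two
    granddaughters observed to 20.2 hr; frame interval 0.2 hr."""
    dt = 0.2
    rows = []

    def add(cid, parent, f0, f1, x0):
        for fi in range(f0, f1 + 1):
            rows.append((cid, parent, fi, round(fi * dt, 6), x0, 10.0, 18.0, 0, 0))

    add("m", "", 0, 50, 5.0)
    add("s1", "m", 51, 130, 4.0)
    add("s2", "m", 51, 130, 6.0)
    add("g1", "s1", 131, 231, 3.0)
    add("g2", "s1", 131, 231, 5.0)
    add("g3", "s2", 131, 231, 7.0)
    add("g4", "s2", 131, 231, 9.0)
    return pd.DataFrame(rows, columns=["cell_id", "parent_id", "frame", "t_hr", "x_um", "y_um", "z_um", "is_paneth", "died"])
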