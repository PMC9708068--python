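"""Population-level statistics: growth-rate fits, fluctuation measures, the
bootstrap independence null for sister symmetry, positional division
histograms and clone-size distributions.

The growth model behind the fit is the Uniform division scheme: each
division increases the proliferating-cell number by alpha on average, so
N(t) = N0 exp(alpha t / T) and the total number of cells ever born follows
U(t) = U0 + N0 (exp(alpha t / T) - 1)/alpha (linear in t as alpha -> 0),
with T the mean cell-cycle time (16.2 hr in the tracked organoids).

Fluctuations are summarized by dwell-time-weighted moments of the
proliferating-cell count; a crypt is called sub-Poissonian when the
standard deviation falls below sqrt(mean), the Poisson birth-death
steady-state benchmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .lineage import EndReason, LineageForest, UndefinedStatisticError
from .models import time_weighted_moments

__all__ = [
    "CountSeries",
    "GrowthFit",
    "BootstrapNullResult",
    "CloneSizeDistribution",
    "fit_growth_rate",
    "fluctuation_stats",
    "bootstrap_symmetry_null",
    "positional_division_histogram",
    "clone_size_distribution",
    "clone_sizes_at",
    "clone_bootstrap_errors",
]

DEFAULT_CYCLE_MEAN_HR = 16.2


class FitError(RuntimeError):
    """Degenerate input to the growth-rate fit."""


@dataclass(frozen=True)
class CountSeries:
    """Per-time counts for one crypt: proliferating cells and total born."""

    times: np.ndarray
    n_proliferating: np.ndarray
    n_total_born: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.n_proliferating, dtype=float)
        u = np.asarray(self.n_total_born, dtype=float)
        if not (len(t) == len(n) == len(u)):
            raise ValueError("times and counts must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(n < 0) or np.any(u < 0):
            raise ValueError("counts must be non-negative")
        if np.any(np.diff(u) < 0):
            raise ValueError("n_total_born must be non-decreasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_proliferating", n)
        object.__setattr__(self, "n_total_born", u)


@dataclass(frozen=True)
class GrowthFit:
    alpha: float
    T: float
    N0: float
    M0: float
    residual: float


def _phi1(y: np.ndarray) -> np.ndarray:
    """(exp(y) - 1)/y, continuous at 0."""
    y = np.asarray(y, dtype=float)
    out = np.ones_like(y)
    nz = np.abs(y) > 1e-8
    out[nz] = np.expm1(y[nz]) / y[nz]
    return out


def growth_curves(t, alpha: float, T: float, N0: float, M0: float) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form N(t) and U(t) of the Uniform growth model."""
    t = np.asarray(t, dtype=float)
    x = alpha * t / T
    n = N0 * np.exp(x)
    u = (M0 + N0) + N0 * (t / T) * _phi1(x)
    return n, u


def fit_growth_rate(series: CountSeries, T: float = DEFAULT_CYCLE_MEAN_HR) -> GrowthFit:
    """Least-squares fit of the closed-form N(t), U(t) with a single alpha.

    N0 and M0 are taken from the first time point; alpha is the only free
    parameter, fitted jointly to both curves by unweighted least squares.
    """
    t = series.times - series.times[0]
    N0 = float(series.n_proliferating[0])
    U0 = float(series.n_total_born[0])
    M0 = U0 - N0
    if len(t) < 3:
        raise FitError("need at least 3 time points")
    if N0 <= 0 or np.all(series.n_proliferating == 0):
        raise FitError("degenerate series: no proliferating cells at start")

    def sse(alpha: float) -> float:
        n, u = growth_curves(t, alpha, T, N0, M0)
        return float(np.sum((n - series.n_proliferating) ** 2) + np.sum((u - series.n_total_born) ** 2))

    res = minimize_scalar(sse, bounds=(-1.0, 1.0), method="bounded", options={"xatol": 1e-10})
    return GrowthFit(alpha=float(res.x), T=T, N0=N0, M0=M0, residual=float(res.fun))


def fluctuation_stats(series: CountSeries) -> tuple[float, float, float, bool]:
    """Dwell-weighted mean, sd, CV of the proliferating-cell count and the
    sub-Poissonian flag (sd < sqrt(mean)).

    The count is treated as piecewise constant: the value at time i holds
    until time i+1 (the final value carries no weight).
    """
    if len(series.times) < 2:
        raise ValueError("need at least 2 time points")
    dt = np.diff(series.times)
    mean, sd = time_weighted_moments(dt, series.n_proliferating[:-1])
    cv = sd / mean if mean > 0 else math.nan
    return mean, sd, cv, bool(sd < math.sqrt(mean))


@dataclass(frozen=True)
class BootstrapNullResult:
    mean_phi: float
    sd_phi: float
    p_value_bound: float
    p_is_upper_bound: bool  # True when no iteration reached the observed value
    n_exceeding: int
    n_iterations: int
    seed: int | None

    def p_label(self) -> str:
        return (f"p < {self.p_value_bound:g}" if self.p_is_upper_bound else f"p = {self.p_value_bound:g}")


def bootstrap_symmetry_null(
    n_pairs: int,
    p_divide: float,
    n_iter: int,
    observed_phi: float = 0.97,
    seed: int | np.random.Generator | None = None,
    chunk: int = 2048,
) -> BootstrapNullResult:
    """Null distribution of the sister symmetry fraction under independence.

    Each iteration draws ``n_pairs`` sister pairs, both members
    independently proliferative with probability ``p_divide``; the
    symmetry fraction is the fraction of concordant pairs.  The p-value
    for the observed fraction is reported as the tail fraction, or as the
    upper bound 1/n_iter when no iteration reaches it (never as zero).
    """
    if not (0.0 <= p_divide <= 1.0):
        raise ValueError("p_divide must be in [0, 1]")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stored_seed = None if isinstance(seed, np.random.Generator) else seed

    phis = np.empty(n_iter)
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        a = rng.random((m, n_pairs)) < p_divide
        b = rng.random((m, n_pairs)) < p_divide
        phis[done : done + m] = (a == b).mean(axis=1)
        done += m
    n_exceed = int(np.sum(phis >= observed_phi))
    if n_exceed > 0:
        p_bound, is_bound = n_exceed / n_iter, False
    else:
        p_bound, is_bound = 1.0 / n_iter, True
    return BootstrapNullResult(
        mean_phi=float(phis.mean()),
        sd_phi=float(phis.std()),
        p_value_bound=p_bound,
        p_is_upper_bound=is_bound,
        n_exceeding=n_exceed,
        n_iterations=n_iter,
        seed=stored_seed,
    )


def positional_division_histogram(
    division_events: pd.DataFrame,
    position_bin_um: float = 10.0,
    time_bin_hr: float = 5.0,
):
    """2-D histogram of division events over (axis position, time) plus the
    time-averaged fractional profile along the axis.

    ``division_events`` needs columns ``t_hr`` and ``p_um`` (axis position
    of the mother at division).  Returns (counts, position_edges,
    time_edges, profile) where ``profile`` sums to 1 over position bins
    (empty input gives an empty histogram and a zero profile).
    """
    t = division_events["t_hr"].to_numpy(dtype=float) if len(division_events) else np.empty(0)
    p = division_events["p_um"].to_numpy(dtype=float) if len(division_events) else np.empty(0)
    p_max = p.max() if len(p) else position_bin_um
    t_max = t.max() if len(t) else time_bin_hr
    p_edges = np.arange(0.0, p_max + position_bin_um, position_bin_um)
    t_edges = np.arange(0.0, t_max + time_bin_hr, time_bin_hr)
    counts, p_edges, t_edges = np.histogram2d(p, t, bins=(p_edges, t_edges))
    total = counts.sum()
    profile = counts.sum(axis=1) / total if total > 0 else np.zeros(len(p_edges) - 1)
    return counts, p_edges, t_edges, profile


@dataclass
class CloneSizeDistribution:
    window: float
    sizes: np.ndarray  # distinct clone sizes, >= 1
    fractions: np.ndarray
    bootstrap_sd: np.ndarray
    n_clones: int
    raw_sizes: list[int] = field(default_factory=list, repr=False)


def _progeny_count(forest: LineageForest, cell_id: str, tau: float):
    """Living descendants of ``cell_id`` at time tau (the cell itself if it
    has not divided).  Returns None if the clone is censored by track loss
    before tau."""
    cell = forest.cells[cell_id]
    if cell.t_end > tau:
        return 1
    if cell.end_reason is EndReason.DIVIDED:
        total = 0
        for kid in forest.children_of(cell_id):
            sub = _progeny_count(forest, kid, tau)
            if sub is None:
                return None
            total += sub
        return total
    if cell.end_reason is EndReason.DIED:
        return 0
    # track ends at or before tau without division or death
    if cell.t_end >= tau:  # observed through the window end
        return 1
    return None  # lost inside the window


def clone_sizes_at(forest: LineageForest, t_start: float, window: float) -> list[int]:
    """Clone sizes for one window [t_start, t_start + window): the number of
    living descendants at the window end of every cell alive at the window
    start.  Clones censored by track loss are dropped, as are clones of
    size zero (the founder died leaving no progeny)."""
    tau = t_start + window
    sizes = []
    for cell in forest.iter_cells():
        if cell.t_birth <= t_start < cell.t_end:
            s = _progeny_count(forest, cell.cell_id, tau)
            if s is not None and s >= 1:
                sizes.append(s)
    return sizes


def clone_size_distribution(
    forest: LineageForest,
    window: float = 40.0,
    stride: float = 1.0,
    n_bootstrap: int = 100,
    seed: int | np.random.Generator | None = None,
    start: float | None = None,
    stop: float | None = None,
) -> CloneSizeDistribution:
    """Pooled clone-size histogram over a sliding window.

    The window start slides in ``stride``-hour steps from the earliest
    birth time (or ``start``) to ``experiment_end - window`` (or ``stop``);
    all windows' clone sizes are pooled.  Bootstrap standard deviations of
    the per-size fractions are computed by resampling clones with
    replacement.
    """
    t0 = min(c.t_birth for c in forest.iter_cells()) if start is None else start
    if forest.experiment_end - t0 < window:
        raise ValueError(f"forest spans less than the {window}-hr window")
    last = forest.experiment_end - window if stop is None else min(stop, forest.experiment_end - window)
    starts = np.arange(t0, last + 1e-9, stride)
    pooled: list[int] = []
    for s in starts:
        pooled.extend(clone_sizes_at(forest, float(s), window))
    if not pooled:
        raise UndefinedStatisticError("no clones observed in any window")
    sizes, counts = np.unique(pooled, return_counts=True)
    fractions = counts / counts.sum()
    sd_by_size = clone_bootstrap_errors(pooled, n_runs=n_bootstrap, seed=seed)
    return CloneSizeDistribution(
        window=window,
        sizes=sizes,
        fractions=fractions,
        bootstrap_sd=np.array([sd_by_size[s] for s in sizes]),
        n_clones=len(pooled),
        raw_sizes=pooled,
    )


def clone_bootstrap_errors(
    clone_sizes,
    n_runs: int = 100,
    seed: int | np.random.Generator | None = None,
) -> dict[int, float]:
    """Per-size standard deviation of the clone-size fractions under
    resampling with replacement of the observed clones (``n_runs`` draws
    of N clones each)."""
    sizes = np.asarray(clone_sizes, dtype=int)
    if len(sizes) < 1:
        raise ValueError("need at least one clone")
    if n_runs < 2:
        raise ValueError("need at least two bootstrap runs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    uniq = np.unique(sizes)
    n = len(sizes)
    fracs = np.empty((n_runs, len(uniq)))
    for k in range(n_runs):
        draw = sizes[rng.integers(0, n, size=n)]
        fracs[k] = (draw[:, None] == uniq[None, :]).mean(axis=0)
    sds = fracs.std(axis=0)
    return {int(s): float(sd) for s, sd in zip(uniq, sds)}
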