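"""Nucleation-rate estimation for multifarious tile systems.

Two models estimate how fast each target shape nucleates under a given
concentration pattern:

* the **Stochastic Greedy Model (SGM)** samples single-tile-addition growth
  paths from every start location.  While any attachment is favourable
  (``dG < 0``) the most favourable one is made deterministically; otherwise an
  unfavourable attachment is chosen with Boltzmann probability
  ``exp(-dG)``.  The highest free energy visited along a path is its
  nucleation barrier; the rate follows an Arrhenius form: equilibrium
  occupancy of each distinct barrier state, ``exp(-G(barrier))``, times the
  summed forward attachment kinetics ``c/u0`` from that state.

* the **Window Nucleation Model (WNM)** is a fast proxy: the Boltzmann weight
  of every fully assembled k-by-k window swept over the shape, i.e.
  ``exp(sum_i ln(c_i/u0) + B_w * G_se)`` with ``B_w = 2k(k-1)`` internal
  bonds, summed over windows.

Both scores are meaningful only relative to each other (the reference
concentration offset cancels); classification takes the argmax over shapes.
Growth paths are confined to one target layout at a time (each location grows
its correct tile); chimeric growth is not sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .energetics import (
    ConcentrationPattern,
    EnergyParams,
    chemical_potential,
)
from .tileset import SIDE_OFFSETS, ShapeLayout, TileSystem

__all__ = [
    "GreedyPath",
    "NucleationEstimate",
    "ClassificationResult",
    "sgm_sample_path",
    "sgm_estimate_rate",
    "wnm_log_score",
    "wnm_score",
    "free_energy_profile",
    "classify_pattern",
]


@dataclass(frozen=True)
class GreedyPath:
    """One sampled growth path and its free-energy trace.

    ``locations[i]`` is the i-th tile added (``locations[0]`` is the start
    monomer); ``energies[i]`` is the assembly free energy after that step.
    The barrier is the maximum energy visited; the barrier state is the
    assembly at that point.
    """

    layout_name: str
    start: tuple[int, int]
    locations: tuple[tuple[int, int], ...]
    energies: tuple[float, ...]
    barrier_index: int

    @property
    def barrier(self) -> float:
        return self.energies[self.barrier_index]

    @property
    def barrier_state(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.locations[: self.barrier_index + 1])

    def __len__(self) -> int:
        return len(self.locations)


@dataclass(frozen=True)
class NucleationEstimate:
    """Aggregated SGM rate estimate for one shape."""

    shape: str
    log_rate: float
    min_barrier: float
    n_paths: int
    n_barrier_states: int
    #: location -> fraction of sampled paths whose barrier state contains it
    participation: dict[tuple[int, int], float]
    #: median barrier-state size over sampled paths (seed-size diagnostic K)
    k_median: float
    #: start location -> minimum barrier seen from that start
    per_start_min_barrier: dict[tuple[int, int], float]

    @property
    def rate(self) -> float:
        return math.exp(self.log_rate)

    def participation_grid(self, layout: ShapeLayout) -> np.ndarray:
        grid = np.full((layout.rows, layout.cols), np.nan)
        for loc in layout.occupancy:
            grid[loc] = self.participation.get(loc, 0.0)
        return grid


def _gmc_by_location(
    layout: ShapeLayout, pattern: ConcentrationPattern, params: EnergyParams
) -> dict[tuple[int, int], float]:
    return {
        loc: chemical_potential(name, pattern, params)
        for loc, name in layout.occupancy.items()
    }


def sgm_sample_path(
    layout: ShapeLayout,
    pattern: ConcentrationPattern,
    params: EnergyParams,
    start: tuple[int, int],
    rng: np.random.Generator,
    commit_margin: float = 10.0,
    size_cap: int | None = None,
    unfavourable_weight: Literal["boltzmann", "linear"] = "boltzmann",
    _gmc: dict[tuple[int, int], float] | None = None,
) -> GreedyPath:
    """Sample one greedy growth path starting from the monomer at ``start``.

    Stops at full coverage of the layout, at ``size_cap`` tiles, or once the
    running free energy has dropped ``commit_margin`` RT below the running
    barrier (the path is then committed to downhill growth and the barrier is
    fixed).
    """
    if start not in layout.occupancy:
        raise ValueError(f"start location {start} is empty in layout {layout.name!r}")
    gmc = _gmc if _gmc is not None else _gmc_by_location(layout, pattern, params)
    g_se = params.g_se
    occ = layout.occupancy

    locs: set[tuple[int, int]] = {start}
    order = [start]
    g = gmc[start] - params.alpha
    energies = [g]
    barrier = g
    barrier_index = 0
    # frontier: empty layout location -> bonds it would form to the state
    frontier: dict[tuple[int, int], int] = {}
    for dr, dc in SIDE_OFFSETS.values():
        nb = (start[0] + dr, start[1] + dc)
        if nb in occ:
            frontier[nb] = 1

    while frontier:
        if size_cap is not None and len(locs) >= size_cap:
            break
        if barrier - g >= commit_margin:
            break
        # attachment free energies on the frontier
        best_loc = None
        best_dg = math.inf
        for loc in frontier:
            dg = gmc[loc] - frontier[loc] * g_se
            if dg < best_dg or (dg == best_dg and (best_loc is None or loc < best_loc)):
                best_dg = dg
                best_loc = loc
        if best_dg < 0.0:
            chosen, dg_chosen = best_loc, best_dg
        else:
            cand = sorted(frontier)
            dgs = np.array([gmc[loc] - frontier[loc] * g_se for loc in cand])
            if unfavourable_weight == "boltzmann":
                w = np.exp(-(dgs - dgs.min()))
            else:  # linear in -dG, shifted to be non-negative
                w = (dgs.max() - dgs) + 1e-12
            w = w / w.sum()
            chosen = cand[int(rng.choice(len(cand), p=w))]
            dg_chosen = float(dgs[cand.index(chosen)])

        locs.add(chosen)
        order.append(chosen)
        g += dg_chosen
        energies.append(g)
        if g > barrier:
            barrier = g
            barrier_index = len(order) - 1
        del frontier[chosen]
        for dr, dc in SIDE_OFFSETS.values():
            nb = (chosen[0] + dr, chosen[1] + dc)
            if nb in occ and nb not in locs:
                frontier[nb] = frontier.get(nb, 0) + 1

    return GreedyPath(
        layout_name=layout.name,
        start=start,
        locations=tuple(order),
        energies=tuple(energies),
        barrier_index=barrier_index,
    )


def _state_energy(
    state: frozenset[tuple[int, int]],
    gmc: dict[tuple[int, int], float],
    params: EnergyParams,
) -> float:
    g = sum(gmc[loc] for loc in state) - params.alpha
    b = 0
    for r, c in state:
        if (r, c + 1) in state:
            b += 1
        if (r + 1, c) in state:
            b += 1
    return g - b * params.g_se


def _forward_log_kinetics(
    state: frozenset[tuple[int, int]],
    layout: ShapeLayout,
    pattern: ConcentrationPattern,
    params: EnergyParams,
) -> float:
    """log of summed forward attachment fluxes c/u0 from a barrier state."""
    total = 0.0
    seen: set[tuple[int, int]] = set()
    for r, c in state:
        for dr, dc in SIDE_OFFSETS.values():
            nb = (r + dr, c + dc)
            if nb in layout.occupancy and nb not in state and nb not in seen:
                seen.add(nb)
                total += pattern[layout.occupancy[nb]] * 1e-9 / params.u0
    if total == 0.0:  # barrier state is the complete layout
        return -math.inf
    return math.log(total)


def sgm_estimate_rate(
    layout: ShapeLayout,
    pattern: ConcentrationPattern,
    params: EnergyParams,
    n_paths: int = 50,
    rng: np.random.Generator | None = None,
    starts: Sequence[tuple[int, int]] | None = None,
    **path_kwargs,
) -> NucleationEstimate:
    """Estimate the shape's nucleation rate from ``n_paths`` SGM paths per start.

    Each *distinct* barrier state (identical occupied set) contributes once:
    ``exp(-G(barrier)) * sum_forward(c/u0)``; the per-shape rate is the sum
    over distinct barrier states.  Rates are accumulated in log space.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    gmc = _gmc_by_location(layout, pattern, params)
    start_list = list(starts) if starts is not None else layout.locations()

    barrier_states: dict[frozenset, float] = {}
    participation_counts: dict[tuple[int, int], int] = {}
    sizes: list[int] = []
    per_start_min: dict[tuple[int, int], float] = {}
    total = 0
    min_barrier = math.inf
    for start in start_list:
        for _ in range(n_paths):
            path = sgm_sample_path(
                layout, pattern, params, start, rng, _gmc=gmc, **path_kwargs
            )
            total += 1
            bs = path.barrier_state
            if bs not in barrier_states:
                barrier_states[bs] = path.barrier
            sizes.append(len(bs))
            for loc in bs:
                participation_counts[loc] = participation_counts.get(loc, 0) + 1
            per_start_min[start] = min(per_start_min.get(start, math.inf), path.barrier)
            min_barrier = min(min_barrier, path.barrier)

    log_terms = [
        -g + _forward_log_kinetics(bs, layout, pattern, params)
        for bs, g in barrier_states.items()
    ]
    log_rate = float(logsumexp(log_terms)) if log_terms else -math.inf
    return NucleationEstimate(
        shape=layout.name,
        log_rate=log_rate,
        min_barrier=min_barrier,
        n_paths=total,
        n_barrier_states=len(barrier_states),
        participation={loc: n / total for loc, n in participation_counts.items()},
        k_median=float(np.median(sizes)),
        per_start_min_barrier=per_start_min,
    )


def wnm_log_score(
    layout: ShapeLayout,
    pattern: ConcentrationPattern,
    params: EnergyParams,
    k: int = 2,
) -> float:
    """log WNM score: log-sum over fully occupied k-by-k windows of their
    equilibrium weight ``exp(sum_i ln(c_i/u0) + B_w * G_se)``."""
    if k < 1:
        raise ValueError("window size k must be >= 1")
    occ = layout.occupancy
    b_w = 2 * k * (k - 1)
    log_terms: list[float] = []
    for r0 in range(layout.rows - k + 1):
        for c0 in range(layout.cols - k + 1):
            cells = [(r, c) for r in range(r0, r0 + k) for c in range(c0, c0 + k)]
            if all(cell in occ for cell in cells):
                s = sum(
                    math.log(pattern[occ[cell]] * 1e-9 / params.u0) for cell in cells
                )
                log_terms.append(s + b_w * params.g_se)
    if not log_terms:
        raise ValueError(
            f"layout {layout.name!r} contains no fully occupied {k}x{k} window"
        )
    return float(logsumexp(log_terms))


def wnm_score(
    layout: ShapeLayout,
    pattern: ConcentrationPattern,
    params: EnergyParams,
    k: int = 2,
) -> float:
    return math.exp(wnm_log_score(layout, pattern, params, k))


def free_energy_profile(
    paths: Sequence[GreedyPath],
    layout: ShapeLayout,
    pattern: ConcentrationPattern,
    params: EnergyParams,
) -> pd.DataFrame:
    """Free energy versus assembly size over the states visited by paths.

    For each size ``n`` reports the minimum free energy over distinct sampled
    states (``g_min``) and the macrostate aggregate
    ``g_macro = -log sum exp(-G)`` over those states.  In nucleation-limited
    regimes the profile has a maximum at the barrier size.
    """
    if not paths:
        raise ValueError("need at least one sampled path")
    gmc = _gmc_by_location(layout, pattern, params)
    states: dict[int, dict[frozenset, float]] = {}
    for path in paths:
        running: set[tuple[int, int]] = set()
        for loc, g in zip(path.locations, path.energies):
            running.add(loc)
            states.setdefault(len(running), {})[frozenset(running)] = g
    rows = []
    for n in sorted(states):
        gs = np.array(list(states[n].values()))
        rows.append(
            {
                "size": n,
                "g_min": float(gs.min()),
                "g_macro": float(-logsumexp(-gs)),
                "n_states": len(gs),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of classifying a concentration pattern by nucleation."""

    method: str
    #: shape name -> log rate (SGM) or log score (WNM)
    log_scores: dict[str, float]
    predicted: str | None  # None iff tie
    margin: float  # log(best) - logsumexp(others); 0 for a 1-shape system
    is_tie: bool

    def ranking(self) -> list[tuple[str, float]]:
        return sorted(self.log_scores.items(), key=lambda kv: -kv[1])


def classify_pattern(
    pattern: ConcentrationPattern,
    system: TileSystem,
    params: EnergyParams,
    method: Literal["sgm", "wnm"] = "wnm",
    k: int = 2,
    n_paths: int = 25,
    rng: np.random.Generator | None = None,
    tie_tol: float = 1e-9,
    **path_kwargs,
) -> ClassificationResult:
    """Predict which shape nucleates for a pattern: argmax of per-shape rates.

    Ties (top two log scores within ``tie_tol``) are reported explicitly with
    ``predicted=None`` rather than broken silently.
    """
    if method not in ("sgm", "wnm"):
        raise ValueError("method must be 'sgm' or 'wnm'")
    if not system.layouts:
        raise ValueError("system has no layouts to classify against")
    log_scores: dict[str, float] = {}
    for layout in system.layouts:
        if method == "wnm":
            log_scores[layout.name] = wnm_log_score(layout, pattern, params, k)
        else:
            est = sgm_estimate_rate(
                layout, pattern, params, n_paths=n_paths, rng=rng, **path_kwargs
            )
            log_scores[layout.name] = est.log_rate
    ranked = sorted(log_scores.items(), key=lambda kv: (-kv[1], kv[0]))
    best_name, best = ranked[0]
    others = [v for _, v in ranked[1:]]
    is_tie = len(ranked) > 1 and abs(best - ranked[1][1]) <= tie_tol
    margin = float(best - logsumexp(others)) if others else 0.0
    return ClassificationResult(
        method=method,
        log_scores=log_scores,
        predicted=None if is_tie else best_name,
        margin=margin,
        is_tie=is_tie,
    )
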