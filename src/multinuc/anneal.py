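"""Temperature protocols and a winner-take-all competition model.

Protocols are piecewise-linear temperature schedules.  The named presets
mirror the experimental anneals: a fast pre-ramp from 71 to 53 C over 40 min,
a 1 C/h ramp down to the initial growth temperature, the main growth segment
(constant hold or slow ramp), and a final cool to 39.5 C at 1 C per 26 min.

The competition model is a deterministic mean-field caricature of nucleation
plus growth with shared-resource depletion.  Per shape ``s`` with layout
``L_s`` it integrates

    dN_s/dt = k_n * min(WNM_s(c(t), T(t)) * u0, c_scarce)   (nucleation,
                                                             nM of assemblies)
    dA_s/dt = k_g * N_s * max(0, <c_i - c_eq(T)>_i)          (growth, nM of tiles)

The WNM score times the reference concentration is the equilibrium
concentration of assembled critical windows; it is capped by the scarcest
free member tile, since an equilibrium occupancy cannot exceed its limiting
species.  This cap is what makes nucleation rate-limited near the window
melting point and gives anneal speed its leverage.

where ``c(t)`` are free tile concentrations, depleted pro rata by growth
(an assembly draws each of its constituent tiles equally), ``A_s`` is capped
at ``N_s |L_s|`` (assemblies complete), nucleation of a shape shuts off when
any required tile falls to a floor fraction of its initial value, and
consumption is jointly clipped so free concentrations never go negative.
Tile conservation (free + incorporated = initial) holds exactly by
bookkeeping and is asserted each step.  Because nucleation of the on-target
shape depletes tiles shared with competing shapes, slow anneals give the
early-nucleating shape time to starve the others — the winner-take-all
effect; with disjoint tile sets the same slow anneal instead gives off-target
nucleation more time, so selectivity moves the opposite way.

Only rate *ratios* are meaningful; the prefactors set the overall time scale
relative to the anneal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .energetics import ConcentrationPattern, EnergyParams
from .nucleation import sgm_estimate_rate, wnm_log_score
from .tileset import ShapeLayout, TileSystem

__all__ = [
    "TemperatureProtocol",
    "make_protocol",
    "PROTOCOL_PRESETS",
    "rates_vs_temperature",
    "WTAResult",
    "simulate_wta",
]


@dataclass(frozen=True)
class TemperatureProtocol:
    """Piecewise-linear temperature schedule.

    ``segments`` are (start C, end C, duration h); each segment must start at
    the temperature where the previous one ended.  ``main_segment`` marks the
    growth segment whose end defines the growth-time reference.
    """

    segments: tuple[tuple[float, float, float], ...]
    main_segment: int | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        prev_end = None
        for t0, t1, dur in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")
            if prev_end is not None and not math.isclose(t0, prev_end):
                raise ValueError(
                    f"discontinuous protocol: segment starts at {t0} C, "
                    f"previous ended at {prev_end} C"
                )
            prev_end = t1

    @property
    def total_hours(self) -> float:
        return sum(d for _, _, d in self.segments)

    @property
    def growth_end_hours(self) -> float:
        """End time of the main growth segment (total duration if unmarked)."""
        if self.main_segment is None:
            return self.total_hours
        return sum(d for _, _, d in self.segments[: self.main_segment + 1])

    def temperature(self, t_hours: float) -> float:
        """T(t) in C; clamped to the endpoints outside the protocol."""
        if t_hours <= 0:
            return self.segments[0][0]
        elapsed = 0.0
        for t0, t1, dur in self.segments:
            if t_hours <= elapsed + dur:
                frac = (t_hours - elapsed) / dur
                return t0 + frac * (t1 - t0)
            elapsed += dur
        return self.segments[-1][1]


def _preset(t0: float, main: tuple[float, float, float]) -> TemperatureProtocol:
    pre = [(71.0, 53.0, 40.0 / 60.0), (53.0, t0, (53.0 - t0) / 1.0)]
    t_end = main[1]
    final = (t_end, 39.5, (t_end - 39.5) * 26.0 / 60.0)
    return TemperatureProtocol(tuple(pre) + (main,) + (final,), main_segment=2)


PROTOCOL_PRESETS = {
    # constant-temperature flag growth: 47 C held for 51 h
    "flag-constant": _preset(47.0, (47.0, 47.0, 51.0)),
    # flag growth ramp: 48 -> 46 C over 100 h
    "flag-ramp": _preset(48.0, (48.0, 46.0, 100.0)),
    # pattern recognition: 48 -> 45 C over 150 h
    "recognition": _preset(48.0, (48.0, 45.0, 150.0)),
}


def make_protocol(
    spec: str | Sequence[tuple[float, float, float]],
    main_segment: int | None = None,
) -> TemperatureProtocol:
    """Build a protocol from a preset name or explicit segments."""
    if isinstance(spec, str):
        try:
            return PROTOCOL_PRESETS[spec]
        except KeyError:
            raise ValueError(
                f"unknown preset {spec!r}; available: {sorted(PROTOCOL_PRESETS)}"
            ) from None
    return TemperatureProtocol(tuple(spec), main_segment=main_segment)


def _growth_bias(
    layout: ShapeLayout, pattern: ConcentrationPattern, params: EnergyParams
) -> float:
    """Net 2-bond attachment rate over shape sites, in nM.

    Per growth site the net rate is forward attachment minus detachment,
    ``c_i - c_eq`` with the 2-bond equilibrium concentration
    ``c_eq = u0 * e^{-2 G_se}``: bounded by the free concentration (attachment
    is second order) and zero where 2-bond attachment is exactly neutral
    (``2 G_se = G_mc``).  Averaged over the shape's sites and floored at 0.
    """
    c_eq_nm = params.u0 * math.exp(-2.0 * params.g_se) * 1e9
    biases = [
        pattern[name] - c_eq_nm for name in layout.occupancy.values()
    ]
    return max(0.0, float(np.mean(biases)))


def rates_vs_temperature(
    layout: ShapeLayout,
    pattern: ConcentrationPattern,
    params: EnergyParams,
    t_grid_c: Sequence[float],
    method: Literal["wnm", "sgm"] = "wnm",
    k: int = 2,
    n_paths: int = 25,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Nucleation rate and growth bias of one shape across temperatures.

    ``params`` must carry the dH/dS bond model so ``G_se`` follows T.
    Returns a frame with columns temp_C, g_se, log_eta, growth_bias; rates
    are in arbitrary consistent units (only ratios matter).
    """
    if len(t_grid_c) == 0:
        raise ValueError("empty temperature grid")
    rows = []
    for t_c in t_grid_c:
        p_t = params.at_temperature(t_c)
        if method == "wnm":
            log_eta = wnm_log_score(layout, pattern, p_t, k)
        else:
            est = sgm_estimate_rate(layout, pattern, p_t, n_paths=n_paths, rng=rng)
            log_eta = est.log_rate
        rows.append(
            {
                "temp_C": float(t_c),
                "g_se": p_t.g_se,
                "log_eta": float(log_eta),
                "growth_bias": _growth_bias(layout, pattern, p_t),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class WTAResult:
    """Trajectory and summary of a winner-take-all anneal simulation."""

    trajectory: pd.DataFrame
    target: str
    nucleated: dict[str, float]  # cumulative nucleation per shape (nM assemblies)

    @property
    def total_nucleation(self) -> float:
        return float(sum(self.nucleated.values()))

    @property
    def selectivity(self) -> float | None:
        """On-target over total nucleation; None when nothing nucleated."""
        total = self.total_nucleation
        if total == 0.0:
            return None
        return float(self.nucleated[self.target] / total)


def simulate_wta(
    system: TileSystem,
    pattern: ConcentrationPattern,
    protocol: TemperatureProtocol,
    params: EnergyParams,
    target: str,
    dt_hours: float = 0.1,
    k: int = 2,
    k_nucleation: float = 0.1,
    k_growth: float = 3.6,
    floor_frac: float = 0.01,
    conservation_tol: float = 1e-6,
    record_every: int = 10,
) -> WTAResult:
    """Integrate the mean-field nucleation/growth/depletion model.

    Explicit Euler with per-step clipping: nucleation of a shape is limited by
    its scarcest free tile, and total consumption is scaled back jointly so no
    free concentration goes negative.  Aborts with a diagnostic if the
    bookkeeping identity (free + incorporated = initial) drifts beyond
    ``conservation_tol`` — the step size is then too large.
    """
    if target not in system.shape_names:
        raise ValueError(f"target {target!r} names no layout")
    layouts = system.layouts
    tiles = sorted(system.tiles)
    index = {t: i for i, t in enumerate(tiles)}
    init = np.array([pattern[t] for t in tiles])
    free = init.copy()
    members = {
        lay.name: np.array(sorted(index[t] for t in lay.tile_names()))
        for lay in layouts
    }
    n_nuc = {lay.name: 0.0 for lay in layouts}  # nM of assemblies
    a_inc = {lay.name: 0.0 for lay in layouts}  # nM of incorporated tiles
    floor = floor_frac * init

    temperature_dependent = params.dh is not None and params.ds is not None
    rows = []
    t = 0.0
    step = 0
    total_h = protocol.total_hours
    while t < total_h:
        dt = min(dt_hours, total_h - t)
        t_c = protocol.temperature(t)
        p_t = params.at_temperature(t_c) if temperature_dependent else params
        current = ConcentrationPattern(
            {name: max(free[i], 1e-12) for name, i in index.items()}
        )
        d_nuc = {}
        d_grow = {}
        for lay in layouts:
            m = members[lay.name]
            scarce = float((free[m] - floor[m]).min())
            if scarce <= 0.0:
                d_nuc[lay.name] = 0.0
            else:
                # equilibrium nucleus concentration from the WNM, in nM,
                # capped by the scarcest free member tile (an equilibrium
                # occupancy cannot exceed its limiting species)
                log_nuc_nm = wnm_log_score(lay, current, p_t, k) + math.log(
                    params.u0 * 1e9
                )
                nuc_nm = math.exp(min(log_nuc_nm, 700.0))
                eta = k_nucleation * min(nuc_nm, scarce)
                d_nuc[lay.name] = min(eta * dt, scarce)
            growing = max(0.0, n_nuc[lay.name] * len(lay) - a_inc[lay.name])
            if growing <= 0.0:
                d_grow[lay.name] = 0.0
            else:
                g = k_growth * _growth_bias(lay, current, p_t)
                d_grow[lay.name] = min(g * n_nuc[lay.name] * dt, growing)
        # joint clipping: consumption may not push any free conc below zero
        demand = np.zeros_like(free)
        for lay in layouts:
            if d_grow[lay.name] > 0.0:
                demand[members[lay.name]] += d_grow[lay.name] / len(lay)
        over = demand > free
        gamma = float((free[over] / demand[over]).min()) if over.any() else 1.0
        for lay in layouts:
            d_grow[lay.name] *= gamma
        demand *= gamma

        free = free - demand
        for lay in layouts:
            n_nuc[lay.name] += d_nuc[lay.name]
            a_inc[lay.name] += d_grow[lay.name]

        # conservation: free + sum_s A_s/|L_s| (per member tile) == init
        recon = free.copy()
        for lay in layouts:
            recon[members[lay.name]] += a_inc[lay.name] / len(lay)
        drift = float(np.abs(recon - init).max())
        if drift > conservation_tol * max(1.0, float(init.max())):
            raise RuntimeError(
                f"tile conservation violated by {drift:.3g} nM at t={t:.2f} h; "
                f"reduce dt_hours (currently {dt_hours})"
            )
        if step % record_every == 0 or t + dt >= total_h:
            total = sum(n_nuc.values())
            row = {"time_h": t + dt, "temp_C": t_c}
            for lay in layouts:
                row[f"nucleated_{lay.name}"] = n_nuc[lay.name]
                row[f"incorporated_{lay.name}"] = a_inc[lay.name]
            row["selectivity"] = n_nuc[target] / total if total > 0 else np.nan
            rows.append(row)
        t += dt
        step += 1

    return WTAResult(
        trajectory=pd.DataFrame(rows), target=target, nucleated=dict(n_nuc)
    )
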