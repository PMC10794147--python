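"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as direct enumeration, separate from
the package's optimised code paths, so tests compare two independent routes.
"""

from __future__ import annotations

import itertools
import math

from multinuc.tileset import (
    OPPOSITE,
    SIDES,
    SIDE_OFFSETS,
    ShapeLayout,
    TileSystem,
    complement,
)


def state_free_energy(locs, layout, conc_nm, g_se, u0=1.0):
    """G of a set of layout locations, by direct summation (alpha = 0)."""
    g = 0.0
    for loc in locs:
        g += -math.log(conc_nm[layout.occupancy[loc]] * 1e-9 / u0)
    bonds = 0
    for r, c in locs:
        if (r, c + 1) in locs:
            bonds += 1
        if (r + 1, c) in locs:
            bonds += 1
    return g - bonds * g_se


def _neighbors(loc):
    r, c = loc
    return [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]


def minimax_barrier(layout: ShapeLayout, conc_nm, g_se, u0=1.0) -> float:
    """Minimum achievable nucleation barrier over all single-tile growth orders.

    Exhaustive minimax shortest path over the lattice of connected
    subassemblies, from any starting monomer to the complete layout.  Only
    feasible for small layouts (uses frozensets of locations as states).
    """
    import heapq

    occ = set(layout.occupancy)
    full = frozenset(occ)
    best: dict[frozenset, float] = {}
    heap = []
    for loc in occ:
        s = frozenset([loc])
        g = state_free_energy(s, layout, conc_nm, g_se, u0)
        best[s] = g
        heapq.heappush(heap, (g, tuple(sorted(s))))
    while heap:
        val, key = heapq.heappop(heap)
        state = frozenset(key)
        if best.get(state, math.inf) < val:
            continue
        if state == full:
            return val
        frontier = {
            nb for loc in state for nb in _neighbors(loc) if nb in occ
        } - state
        for nb in frontier:
            new = state | {nb}
            g_new = state_free_energy(new, layout, conc_nm, g_se, u0)
            cand = max(val, g_new)
            if cand < best.get(frozenset(new), math.inf):
                best[frozenset(new)] = cand
                heapq.heappush(heap, (cand, tuple(sorted(new))))
    raise RuntimeError("layout not connected")


def _bonds_at(system: TileSystem, layout, loc, tile, extra=None, exclude=()):
    """Sides on which `tile` placed at `loc` bonds a neighbouring tile.

    Neighbours are the layout's correct tiles, plus `extra` (location ->
    tile name) overrides, minus excluded locations.
    """
    occ = dict(layout.occupancy)
    if extra:
        occ.update(extra)
    sides = []
    for s in SIDES:
        nb = (loc[0] + SIDE_OFFSETS[s][0], loc[1] + SIDE_OFFSETS[s][1])
        if nb in exclude or nb not in occ or nb == loc:
            continue
        g1 = system.tiles[tile].glues[s]
        g2 = system.tiles[occ[nb]].glues[OPPOSITE[s]]
        if g1 is not None and g2 == complement(g1):
            sides.append(s)
    return sides


def brute_self_healing(system: TileSystem) -> list:
    """All (layout, location, wrong tile) where a wrong tile bonds >= 2 sides."""
    bad = []
    for layout in system.layouts:
        for loc, correct in layout.occupancy.items():
            for name in system.tiles:
                if name == correct:
                    continue
                if len(_bonds_at(system, layout, loc, name)) >= 2:
                    bad.append((layout.name, loc, name))
    return bad


def brute_second_order(system: TileSystem) -> list:
    """All 2-step error chains: a 1-bond wrong attachment enabling a further
    2-bond attachment that uses the erroneous tile."""
    bad = []
    for layout in system.layouts:
        occ = layout.occupancy
        for loc, correct in occ.items():
            for t in system.tiles:
                if t == correct:
                    continue
                sides = _bonds_at(system, layout, loc, t)
                if len(sides) != 1:
                    continue
                bonded = (
                    loc[0] + SIDE_OFFSETS[sides[0]][0],
                    loc[1] + SIDE_OFFSETS[sides[0]][1],
                )
                for l2 in _neighbors(loc):
                    if l2 == bonded:
                        continue
                    for t2 in system.tiles:
                        if t2 == occ.get(l2):
                            continue
                        sides2 = _bonds_at(
                            system, layout, l2, t2, extra={loc: t}, exclude=()
                        )
                        if len(sides2) < 2:
                            continue
                        # at least one bond must be to the erroneous tile
                        to_t = any(
                            (l2[0] + SIDE_OFFSETS[s][0], l2[1] + SIDE_OFFSETS[s][1])
                            == loc
                            for s in sides2
                        )
                        if to_t:
                            bad.append((layout.name, loc, t, l2, t2))
    return bad
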