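"""Miniature stand-in systems for tests, examples and demonstrations.

The published system draws three 24x24 letter shapes (H, A, M) sharing one
pool of 917 tiles.  Everything here is a scaled-down synthetic analogue so
that every operation in the package can be exercised quickly and offline:

* :func:`mini_ham_masks` / :func:`make_fixture_system` — three 5x5 letter
  masks whose fully unique design has 40 tiles, small enough for exhaustive
  proofreading oracles; optionally merged by the merge designer.
* :func:`make_shared_block_fixture` — a hand-built shared-tile system in the
  spirit of the published S + H + A + M construction: shared tiles sit on one
  chequerboard sublattice and recur in every shape in different spatial
  arrangements, while interaction tiles on the other sublattice are unique to
  each shape.  This fixture is for nucleation, pattern and anneal studies,
  where only layout occupancy and concentrations matter; its tiles carry null
  glues only, so it is not a glue-valid design (use the merge designer for
  those).
"""

from __future__ import annotations

import numpy as np

from .energetics import ConcentrationPattern
from .merge import run_merging
from .tileset import ShapeLayout, Tile, TileSystem, build_unique_design

__all__ = [
    "mini_ham_masks",
    "make_fixture_system",
    "make_shared_block_fixture",
    "make_wta_inputs",
]

_MINI = {
    "H": [
        "X...X",
        "X...X",
        "XXXXX",
        "X...X",
        "X...X",
    ],
    "A": [
        ".XXX.",
        ".X.X.",
        "XXXXX",
        "X...X",
        "X...X",
    ],
    "M": [
        "X...X",
        "XX.XX",
        "XXXXX",
        "X...X",
        "X...X",
    ],
}


def mini_ham_masks() -> dict[str, list[list[bool]]]:
    """Three 5x5 letter occupancy masks (H: 13, A: 14, M: 15 cells)."""
    return {
        name: [[ch == "X" for ch in row] for row in rows]
        for name, rows in _MINI.items()
    }


def make_fixture_system(
    seed: int = 1,
    merged: bool = False,
    restarts: int = 1,
    masks: dict | None = None,
) -> TileSystem:
    """Mini H/A/M system: the fully unique design of the 5x5 letter masks.

    With ``merged=True`` the unique design is additionally run through the
    merge designer (seeded, hence deterministic) and the merged system is
    returned.
    """
    system = build_unique_design(masks if masks is not None else mini_ham_masks())
    if merged:
        system, _ = run_merging(system, seed, restarts=restarts)
    return system


def make_shared_block_fixture(
    seed: int = 1,
    n: int = 10,
    shape_names: tuple[str, ...] = ("H", "A", "M"),
    shared: bool = True,
) -> TileSystem:
    """Shared-tile block fixture for nucleation and pattern studies.

    Each shape is a fully occupied n-by-n block.  Shared tiles ``s0, s1, ...``
    occupy the even chequerboard sublattice ((row+col) % 2 == 0) of every
    shape — in row-major order in the first shape and in a seeded random
    arrangement in each further shape, emulating tiles that are colocalized
    in one structure but scattered in the others.  The odd sublattice holds
    interaction tiles unique to each shape (``H_u0, ...``).

    With ``shared=False`` every shape instead gets entirely its own tiles
    (a no-shared-components control with identical geometry).

    Tiles carry only null glues: this fixture defines occupancy, sharing and
    concentration structure, not a glue-valid design.
    """
    rng = np.random.default_rng(seed)
    even = [(r, c) for r in range(n) for c in range(n) if (r + c) % 2 == 0]
    odd = [(r, c) for r in range(n) for c in range(n) if (r + c) % 2 == 1]
    null_tile = {"N": None, "E": None, "S": None, "W": None}

    tiles: dict[str, Tile] = {}
    layouts: list[ShapeLayout] = []
    shared_names = [f"s{i}" for i in range(len(even))]
    if shared:
        for name in shared_names:
            tiles[name] = Tile(name, null_tile)
    for k, shape in enumerate(shape_names):
        occ: dict[tuple[int, int], str] = {}
        if shared:
            order = list(range(len(even)))
            if k > 0:
                order = list(rng.permutation(len(even)))
            for slot, idx in zip(even, order):
                occ[slot] = shared_names[idx]
        else:
            for i, slot in enumerate(even):
                name = f"{shape}_s{i}"
                tiles[name] = Tile(name, null_tile)
                occ[slot] = name
        for j, slot in enumerate(odd):
            name = f"{shape}_u{j}"
            tiles[name] = Tile(name, null_tile)
            occ[slot] = name
        layouts.append(ShapeLayout(shape, n, n, occ))
    return TileSystem(tiles=tiles, glue_alphabet=set(), layouts=layouts)


def make_wta_inputs(
    shared: bool = True,
    seed: int = 1,
    n: int = 10,
    target: str = "H",
    window: int = 5,
    base_nm: float = 50.0,
    enhanced_nm: float = 880.0,
) -> tuple[TileSystem, ConcentrationPattern]:
    """Two-shape system plus an on-target flag pattern for anneal studies.

    Builds the two-shape block fixture (shared tile pool, or disjoint pools
    as the no-shared-components control) and a concentration pattern that
    enhances the chequerboard-sublattice tiles inside a central window of the
    target shape.  In the shared variant these enhanced tiles are colocalized
    in the target but scattered in the competitor; in the disjoint control
    the same positions of the target shape are enhanced.
    """
    system = make_shared_block_fixture(
        seed=seed, n=n, shape_names=(target, "B" if target != "B" else "C"),
        shared=shared,
    )
    layout = system.layout(target)
    r0 = n // 2 - window // 2
    cells = [
        (r, c)
        for r in range(r0, r0 + window)
        for c in range(r0, r0 + window)
    ]
    enhanced = {
        layout.occupancy[(r, c)] for (r, c) in cells if (r + c) % 2 == 0
    }
    pattern = ConcentrationPattern(
        {t: (enhanced_nm if t in enhanced else base_nm) for t in system.tiles}
    )
    return system, pattern
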