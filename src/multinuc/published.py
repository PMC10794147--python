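"""Checks against the published 24x24 three-shape system.

The full-scale system (three 24x24 letter shapes sharing 917 tiles) is
distributed as supplementary data by its authors and is *optional input*, not
a built-in constant.  Given a directory holding the three merged shape
layouts as text grids (``H.layout``, ``A.layout``, ``M.layout``; tokens are
tile names, ``.`` marks empty cells), this module recomputes the headline
design statistics: the size of the fully unique initial design (tiles and
glue pairs) from the occupancy masks, and the sharing split of the merged
tile set.
"""

from __future__ import annotations

import os

from .tileset import TileSystem, Tile, build_unique_design, read_layout, sharing_stats

__all__ = ["PUBLISHED_LAYOUT_FILES", "published_design_report"]

PUBLISHED_LAYOUT_FILES = ("H.layout", "A.layout", "M.layout")


def published_design_report(layout_dir: str) -> dict[str, int]:
    """Recompute design statistics from the published merged shape layouts.

    Returns a dict with the unique-design tile and glue-pair counts (built
    fresh from the occupancy masks) and the merged system's tile sharing
    counts (tiles in exactly one / exactly two / all three shapes, and in at
    least two).
    """
    layouts = []
    for fname in PUBLISHED_LAYOUT_FILES:
        path = os.path.join(layout_dir, fname)
        if not os.path.exists(path):
            raise FileNotFoundError(
                f"published layout file {path!r} not found; download the shape "
                "layouts from the supplementary data archive and save them as "
                f"text grids named {PUBLISHED_LAYOUT_FILES}"
            )
        layouts.append(read_layout(path, name=fname.split(".")[0]))

    masks = {
        lay.name: [
            [(r, c) in lay.occupancy for c in range(lay.cols)]
            for r in range(lay.rows)
        ]
        for lay in layouts
    }
    unique = build_unique_design(masks)

    null = {"N": None, "E": None, "S": None, "W": None}
    names = set().union(*(lay.tile_names() for lay in layouts))
    merged = TileSystem(
        tiles={n: Tile(n, null) for n in names},
        glue_alphabet=set(),
        layouts=layouts,
    )
    stats = sharing_stats(merged)
    return {
        "unique_design_tiles": len(unique.tiles),
        "unique_design_glue_pairs": unique.n_glue_pairs(),
        "merged_tiles": stats.total_tiles,
        "tiles_in_one_shape": stats.unique,
        "tiles_in_two_shapes": stats.in_two,
        "tiles_in_all_shapes": stats.in_all,
        "tiles_shared": stats.shared,
    }
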