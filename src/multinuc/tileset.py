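"""Core domain types for square-lattice tile systems.

A tile is an abstract square with four labelled binding sites ("glues"), one
per side (N, E, S, W).  A glue binds exactly one partner: the glue whose label
is its starred complement (``"708"`` binds ``"708*"``).  A *null* glue binds
nothing and is used on shape edges.  A shape layout places named tiles on a
bounded canvas; a tile system bundles tiles, the glue alphabet and any number
of layouts.  Physically each tile is a 42-nt single-stranded DNA strand with
alternating 10- and 11-nt binding domains, but everything here stays at the
abstract square-tile level.

Conventions (fixed throughout the package):

* coordinates are 0-based, row-major: N = (r-1, c), S = (r+1, c),
  W = (r, c-1), E = (r, c+1);
* connectivity is the 4-neighbourhood; diagonal contacts carry no bonds;
* sides bind N<->S and E<->W, with label complementarity;
* the complement of label ``g`` is ``g + "*"``, and of ``g*`` is ``g``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

__all__ = [
    "SIDES",
    "OPPOSITE",
    "SIDE_OFFSETS",
    "SST_DOMAIN_LENGTHS",
    "sst_strand_length",
    "complement",
    "Glue",
    "Tile",
    "ShapeLayout",
    "TileSystem",
    "SharingStats",
    "Violation",
    "TilesetError",
    "validate_layout",
    "build_unique_design",
    "sharing_stats",
    "read_tileset",
    "write_tileset",
    "read_layout",
    "write_layout",
    "export_xgrow",
]

SIDES = ("N", "E", "S", "W")
OPPOSITE = {"N": "S", "S": "N", "E": "W", "W": "E"}
SIDE_OFFSETS = {"N": (-1, 0), "E": (0, 1), "S": (1, 0), "W": (0, -1)}

#: Domain lengths of the single-stranded tile (SST) motif, in nucleotides.
#: Each tile strand carries four binding domains, alternating 10 and 11 nt.
SST_DOMAIN_LENGTHS = (10, 11, 10, 11)


def sst_strand_length(domains: Sequence[int] = SST_DOMAIN_LENGTHS) -> int:
    """Total strand length in nucleotides of an SST tile motif."""
    return int(sum(domains))


class TilesetError(ValueError):
    """Raised for malformed tile systems, layouts or documents."""


def complement(label: str | None) -> str | None:
    """Complementary glue label: ``"9" <-> "9*"``.  Null stays null."""
    if label is None:
        return None
    return label[:-1] if label.endswith("*") else label + "*"


@dataclass(frozen=True)
class Glue:
    """A binding site label.  ``Glue(None)`` is the null glue."""

    label: str | None

    @property
    def is_null(self) -> bool:
        return self.label is None

    def matches(self, other: "Glue") -> bool:
        """True iff the two glues bind (label complementarity; null binds nothing)."""
        if self.is_null or other.is_null:
            return False
        return other.label == complement(self.label)


@dataclass(frozen=True)
class Tile:
    """A named square tile with one glue label per side (None = null glue)."""

    name: str
    glues: Mapping[str, str | None]

    def __post_init__(self) -> None:
        if set(self.glues) != set(SIDES):
            raise TilesetError(
                f"tile {self.name!r} must have exactly the four sides {SIDES}"
            )
        object.__setattr__(self, "glues", dict(self.glues))

    def glue(self, side: str) -> str | None:
        return self.glues[side]

    @property
    def signature(self) -> tuple[str | None, ...]:
        """Four-glue signature (N, E, S, W); tiles are the same type iff equal."""
        return tuple(self.glues[s] for s in SIDES)

    def null_sides(self) -> frozenset[str]:
        return frozenset(s for s in SIDES if self.glues[s] is None)


@dataclass
class ShapeLayout:
    """Placement of tiles on a bounded canvas.

    ``occupancy`` maps (row, col) -> tile name; each tile name may occur at
    most once per layout.
    """

    name: str
    rows: int
    cols: int
    occupancy: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, tuple[int, int]] = {}
        for (r, c), t in self.occupancy.items():
            if not (0 <= r < self.rows and 0 <= c < self.cols):
                raise TilesetError(f"layout {self.name!r}: location {(r, c)} off-canvas")
            if t in seen:
                raise TilesetError(
                    f"layout {self.name!r}: tile {t!r} at both {seen[t]} and {(r, c)}"
                )
            seen[t] = (r, c)

    def __len__(self) -> int:
        return len(self.occupancy)

    def locations(self) -> list[tuple[int, int]]:
        return sorted(self.occupancy)

    def tile_names(self) -> set[str]:
        return set(self.occupancy.values())

    def neighbor(self, loc: tuple[int, int], side: str) -> tuple[int, int]:
        dr, dc = SIDE_OFFSETS[side]
        return (loc[0] + dr, loc[1] + dc)

    def internal_edges(self) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        """Adjacent occupied pairs, each counted once as (loc, E/S-neighbor)."""
        out = []
        for loc in self.occupancy:
            for side in ("E", "S"):
                nb = self.neighbor(loc, side)
                if nb in self.occupancy:
                    out.append((loc, nb))
        return sorted(out)

    def is_connected(self) -> bool:
        if not self.occupancy:
            return False
        locs = set(self.occupancy)
        stack = [next(iter(locs))]
        seen = {stack[0]}
        while stack:
            loc = stack.pop()
            for side in SIDES:
                nb = (loc[0] + SIDE_OFFSETS[side][0], loc[1] + SIDE_OFFSETS[side][1])
                if nb in locs and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(locs)


@dataclass
class TileSystem:
    """A set of tiles, their glue alphabet and the layouts that use them."""

    tiles: dict[str, Tile]
    glue_alphabet: set[str]
    layouts: list[ShapeLayout] = field(default_factory=list)

    def __post_init__(self) -> None:
        for tile in self.tiles.values():
            for side in SIDES:
                g = tile.glues[side]
                if g is not None and g not in self.glue_alphabet:
                    raise TilesetError(
                        f"tile {tile.name!r} uses undeclared glue {g!r}"
                    )
        for layout in self.layouts:
            missing = layout.tile_names() - set(self.tiles)
            if missing:
                raise TilesetError(
                    f"layout {layout.name!r} references unknown tiles {sorted(missing)}"
                )

    def layout(self, name: str) -> ShapeLayout:
        for lay in self.layouts:
            if lay.name == name:
                return lay
        raise KeyError(name)

    @property
    def shape_names(self) -> list[str]:
        return [lay.name for lay in self.layouts]

    def tile_at(self, layout: ShapeLayout, loc: tuple[int, int]) -> Tile:
        return self.tiles[layout.occupancy[loc]]

    def n_glue_pairs(self) -> int:
        """Number of complementary non-null glue pairs (binding domains)."""
        pairs = {frozenset((g, complement(g))) for g in self.glue_alphabet}
        return len(pairs)

    def copy(self) -> "TileSystem":
        return TileSystem(
            tiles=dict(self.tiles),
            glue_alphabet=set(self.glue_alphabet),
            layouts=[
                ShapeLayout(l.name, l.rows, l.cols, dict(l.occupancy))
                for l in self.layouts
            ],
        )


@dataclass(frozen=True)
class SharingStats:
    """How many tile types occur in exactly 1, exactly 2, ... layouts.

    ``by_multiplicity[m]`` is the number of tile types present in exactly
    ``m`` distinct layouts (tiles absent from every layout count under m=0).
    """

    by_multiplicity: tuple[int, ...]
    total_tiles: int
    total_glue_pairs: int

    @property
    def unique(self) -> int:
        return self.by_multiplicity[1] if len(self.by_multiplicity) > 1 else 0

    @property
    def in_two(self) -> int:
        return self.by_multiplicity[2] if len(self.by_multiplicity) > 2 else 0

    @property
    def in_all(self) -> int:
        return self.by_multiplicity[-1]

    @property
    def shared(self) -> int:
        """Tiles present in at least two layouts."""
        return sum(self.by_multiplicity[2:])


@dataclass(frozen=True)
class Violation:
    """One broken layout invariant, located for diagnosis."""

    layout: str
    location: tuple[int, int]
    side: str
    rule: str  # "internal-mismatch" | "boundary-not-null"
    message: str


def validate_layout(system: TileSystem, layout: ShapeLayout) -> list[Violation]:
    """Check the two edge invariants of a layout against a tile system.

    Every internal edge between occupied locations must carry complementary
    glues, and every boundary edge (neighbour empty or off-canvas) must carry
    a null glue.  Returns an empty list iff the layout is valid.
    """
    violations: list[Violation] = []
    for loc in layout.locations():
        tile = system.tiles.get(layout.occupancy[loc])
        if tile is None:
            raise TilesetError(f"unknown tile {layout.occupancy[loc]!r}")
        for side in SIDES:
            nb = layout.neighbor(loc, side)
            g = tile.glues[side]
            if nb in layout.occupancy:
                if side in ("E", "S"):  # each internal edge checked once
                    other = system.tiles[layout.occupancy[nb]]
                    g2 = other.glues[OPPOSITE[side]]
                    if g is None or g2 != complement(g):
                        violations.append(
                            Violation(
                                layout.name, loc, side, "internal-mismatch",
                                f"{tile.name}.{side}={g!r} vs "
                                f"{other.name}.{OPPOSITE[side]}={g2!r}",
                            )
                        )
            else:
                if g is not None:
                    violations.append(
                        Violation(
                            layout.name, loc, side, "boundary-not-null",
                            f"{tile.name}.{side}={g!r} faces empty space",
                        )
                    )
    return violations


def build_unique_design(
    masks: Mapping[str, Sequence[Sequence[bool]]] | Mapping[str, "object"],
) -> TileSystem:
    """Construct the fully unique initial design from occupancy masks.

    Each occupied location of each mask gets a fresh tile; each internal edge
    gets a fresh complementary glue pair; boundary edges get null glues.  Tile
    names are ``{shape}_r{r}c{c}``, glue labels sequential integers with the
    starred label on the S/W side of the edge.

    Parameters
    ----------
    masks
        Mapping shape name -> 2-D boolean occupancy grid (list of rows or
        array).  Each mask must be non-empty and 4-connected.
    """
    tiles: dict[str, Tile] = {}
    alphabet: set[str] = set()
    layouts: list[ShapeLayout] = []
    counter = 0
    for shape, mask in masks.items():
        grid = [[bool(v) for v in row] for row in mask]
        rows, cols = len(grid), len(grid[0]) if grid else 0
        if any(len(row) != cols for row in grid):
            raise TilesetError(f"mask {shape!r} is ragged")
        occ = {
            (r, c): f"{shape}_r{r}c{c}"
            for r in range(rows)
            for c in range(cols)
            if grid[r][c]
        }
        if not occ:
            raise TilesetError(f"mask {shape!r} is empty")
        layout = ShapeLayout(shape, rows, cols, occ)
        if not layout.is_connected():
            raise TilesetError(f"mask {shape!r} is not 4-connected")
        glue_of: dict[tuple[tuple[int, int], str], str] = {}
        for loc, nb in layout.internal_edges():
            counter += 1
            label = str(counter)
            side = "E" if nb == (loc[0], loc[1] + 1) else "S"
            glue_of[(loc, side)] = label
            glue_of[(nb, OPPOSITE[side])] = label + "*"
            alphabet.update((label, label + "*"))
        for loc, name in occ.items():
            glues = {side: glue_of.get((loc, side)) for side in SIDES}
            tiles[name] = Tile(name, glues)
        layouts.append(layout)
    return TileSystem(tiles=tiles, glue_alphabet=alphabet, layouts=layouts)


def sharing_stats(system: TileSystem) -> SharingStats:
    """Count tile types by the number of distinct layouts containing them."""
    if not system.layouts:
        raise TilesetError("system has no layouts")
    n_layouts = len(system.layouts)
    mult = [0] * (n_layouts + 1)
    for name in system.tiles:
        m = sum(name in lay.tile_names() for lay in system.layouts)
        mult[m] += 1
    return SharingStats(
        by_multiplicity=tuple(mult),
        total_tiles=len(system.tiles),
        total_glue_pairs=system.n_glue_pairs(),
    )


# ---------------------------------------------------------------------------
# I/O: tileset JSON documents and layout text grids
# ---------------------------------------------------------------------------

_FORMAT = "multinuc-tileset"
_VERSION = 1


def write_tileset(system: TileSystem, fp: IO[str] | str) -> None:
    """Write a tile system as a JSON document (schema documented in README)."""
    doc = {
        "format": _FORMAT,
        "version": _VERSION,
        "glues": sorted(system.glue_alphabet),
        "tiles": [
            {"name": t.name, "edges": {s: t.glues[s] for s in SIDES}}
            for t in sorted(system.tiles.values(), key=lambda t: t.name)
        ],
        "layouts": [
            {
                "name": lay.name,
                "rows": lay.rows,
                "cols": lay.cols,
                "grid": [
                    [lay.occupancy.get((r, c), ".") for c in range(lay.cols)]
                    for r in range(lay.rows)
                ],
            }
            for lay in system.layouts
        ],
    }
    if isinstance(fp, str):
        with open(fp, "w") as fh:
            json.dump(doc, fh, indent=1)
    else:
        json.dump(doc, fp, indent=1)


def read_tileset(fp: IO[str] | str, strict: bool = True) -> TileSystem:
    """Read a tile system from a JSON document.

    With ``strict=True`` (default) unknown top-level fields and undeclared
    glues are rejected; otherwise unknown fields are ignored.
    """
    if isinstance(fp, str):
        with open(fp) as fh:
            doc = json.load(fh)
    else:
        doc = json.load(fp)
    known = {"format", "version", "glues", "tiles", "layouts"}
    if strict:
        extra = set(doc) - known
        if extra:
            raise TilesetError(f"unknown document fields {sorted(extra)}")
    if doc.get("format") != _FORMAT:
        raise TilesetError(f"not a {_FORMAT} document")
    alphabet = set(doc["glues"])
    tiles: dict[str, Tile] = {}
    for entry in doc["tiles"]:
        name = entry["name"]
        if name in tiles:
            raise TilesetError(f"duplicate tile name {name!r}")
        glues = {s: entry["edges"].get(s) for s in SIDES}
        if strict:
            for g in glues.values():
                if g is not None and g not in alphabet:
                    raise TilesetError(f"tile {name!r} uses undeclared glue {g!r}")
        else:
            alphabet.update(g for g in glues.values() if g is not None)
        tiles[name] = Tile(name, glues)
    layouts = []
    for entry in doc.get("layouts", []):
        occ = {
            (r, c): cell
            for r, row in enumerate(entry["grid"])
            for c, cell in enumerate(row)
            if cell != "."
        }
        layouts.append(ShapeLayout(entry["name"], entry["rows"], entry["cols"], occ))
    return TileSystem(tiles=tiles, glue_alphabet=alphabet, layouts=layouts)


def write_layout(layout: ShapeLayout, fp: IO[str] | str) -> None:
    """Write a layout as a whitespace-separated text grid ('.' = empty)."""
    lines = []
    for r in range(layout.rows):
        lines.append(
            " ".join(layout.occupancy.get((r, c), ".") for c in range(layout.cols))
        )
    text = "\n".join(lines) + "\n"
    if isinstance(fp, str):
        with open(fp, "w") as fh:
            fh.write(text)
    else:
        fp.write(text)


def read_layout(fp: IO[str] | str, name: str = "shape") -> ShapeLayout:
    """Read a layout text grid; tokens are tile names, '.' marks empty cells."""
    if isinstance(fp, str):
        with open(fp) as fh:
            text = fh.read()
    else:
        text = fp.read()
    rows = [line.split() for line in text.splitlines() if line.strip()]
    if not rows:
        raise TilesetError("empty layout document")
    cols = len(rows[0])
    if any(len(row) != cols for row in rows):
        raise TilesetError("ragged layout grid")
    occ = {
        (r, c): tok
        for r, row in enumerate(rows)
        for c, tok in enumerate(row)
        if tok != "."
    }
    return ShapeLayout(name, len(rows), cols, occ)


def export_xgrow(system: TileSystem, fp: IO[str] | str, gse: float = 8.1) -> None:
    """Best-effort export to the xgrow ``.tiles`` format (for interoperability).

    Null glues are exported as bond 0; each non-null complementary pair
    becomes one numbered xgrow bond type (xgrow glues are self-complementary,
    so the star structure is flattened — hence best-effort).
    """
    pair_index: dict[frozenset, int] = {}
    for g in sorted(system.glue_alphabet):
        key = frozenset((g, complement(g)))
        if key not in pair_index:
            pair_index[key] = len(pair_index) + 1

    def bond(g: str | None) -> int:
        return 0 if g is None else pair_index[frozenset((g, complement(g)))]

    lines = [
        f"num tile types={len(system.tiles)}",
        f"num binding types={len(pair_index)}",
        "tile edges={",
    ]
    for t in sorted(system.tiles.values(), key=lambda t: t.name):
        n, e, s, w = (bond(t.glues[side]) for side in SIDES)
        lines.append(f"{{{n} {e} {s} {w}}}[1]   % {t.name}")
    lines.append("}")
    lines.append("binding strengths={" + " ".join(["1"] * len(pair_index)) + "}")
    lines.append(f"Gse={gse}")
    text = "\n".join(lines) + "\n"
    if isinstance(fp, str):
        with open(fp, "w") as fh:
            fh.write(text)
    else:
        fp.write(text)
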