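"""Stochastic tile merging with self-assembly proofreading criteria.

Starting from a fully unique multi-shape design (one fresh tile per location,
one fresh glue pair per internal edge), the merge designer repeatedly picks
two tiles from two different shapes (with null glues, if any, on the same
sides), identifies them — unifying their glues side by side and propagating
the identification everywhere it occurs — and keeps the merge only if the
modified system still satisfies two criteria from algorithmic self-assembly:

* **self-healing**: at every location of every shape, only the correct tile
  can attach to a correct subassembly by two or more bonds (a wrong tile may
  attach by at most one bond);
* **second-order sensitivity**: a wrong tile attached by one bond must not
  create a neighbourhood where a further wrong tile can attach by two bonds
  (so the initial error tends to fall off rather than get locked in).

Both criteria are evaluated against the full pooled tile set, using the
worst-case neighbourhood (all correct neighbours present); match counts are
monotone under neighbour subsets, so this covers every correct subassembly.
Merging proceeds in two phases: first restricted to an alternating
"chequerboard" parity sublattice (which is likelier to be mergeable), then
over all tiles, each phase running until every eligible pair has been tried
and rejected since the last accepted merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .tileset import (
    OPPOSITE,
    SIDES,
    SIDE_OFFSETS,
    ShapeLayout,
    Tile,
    TileSystem,
    TilesetError,
    complement,
    validate_layout,
)

__all__ = [
    "MergeError",
    "MergeProposal",
    "MergeLog",
    "CriterionReport",
    "SelfHealingWitness",
    "SecondOrderWitness",
    "propose_merge",
    "apply_merge",
    "check_self_healing",
    "check_second_order",
    "run_merging",
]


class MergeError(ValueError):
    """A merge proposal cannot be applied consistently."""


@dataclass(frozen=True)
class MergeProposal:
    """Identify ``tile_b`` with ``tile_a`` (tiles from two different shapes)."""

    tile_a: str
    tile_b: str
    #: per-side pairs of glue labels to unify (complements follow implicitly)
    glue_identifications: tuple[tuple[str, str], ...]

    @property
    def key(self) -> frozenset:
        return frozenset((self.tile_a, self.tile_b))


@dataclass(frozen=True)
class SelfHealingWitness:
    layout: str
    location: tuple[int, int]
    tile: str
    matched_sides: tuple[str, ...]


@dataclass(frozen=True)
class SecondOrderWitness:
    layout: str
    location: tuple[int, int]
    tile: str
    location2: tuple[int, int]
    tile2: str


@dataclass(frozen=True)
class CriterionReport:
    ok: bool
    witnesses: tuple


@dataclass
class MergeLog:
    """Record of one merging run (per restart)."""

    parity: int
    accepted: list[tuple[str, str, str]] = field(default_factory=list)  # phase, a, b
    rejected: list[tuple[str, str, str, str]] = field(default_factory=list)
    tile_counts: list[int] = field(default_factory=list)  # after each accepted merge
    glue_pair_counts: list[int] = field(default_factory=list)


def _tile_layout_locations(
    system: TileSystem,
) -> dict[str, list[tuple[str, tuple[int, int]]]]:
    occ: dict[str, list[tuple[str, tuple[int, int]]]] = {t: [] for t in system.tiles}
    for layout in system.layouts:
        for loc, name in layout.occupancy.items():
            occ[name].append((layout.name, loc))
    return occ


def _eligible_pairs(
    system: TileSystem,
    phase: Literal["chequerboard", "global"],
    parity: int,
) -> list[tuple[str, str]]:
    """All mergeable tile pairs, sorted for a deterministic proposal stream."""
    occ = _tile_layout_locations(system)
    names = sorted(system.tiles)
    infos = {}
    for name in names:
        entries = occ[name]
        if not entries:
            continue
        shapes = {s for s, _ in entries}
        parities = {(r + c) % 2 for _, (r, c) in entries}
        infos[name] = (shapes, parities, system.tiles[name].null_sides())
    pairs = []
    for i, a in enumerate(names):
        if a not in infos:
            continue
        sh_a, par_a, null_a = infos[a]
        for b in names[i + 1 :]:
            if b not in infos:
                continue
            sh_b, par_b, null_b = infos[b]
            if null_a != null_b:
                continue
            # must be drawable from two *different* shapes: some X in shapes(a),
            # Y in shapes(b) with X != Y — false only when both occur in the
            # same single shape
            if len(sh_a) == 1 and sh_a == sh_b:
                continue
            if phase == "chequerboard" and (par_a | par_b) != {parity}:
                continue
            pairs.append((a, b))
    return pairs


def propose_merge(
    system: TileSystem,
    rng: np.random.Generator,
    phase: Literal["chequerboard", "global"] = "global",
    parity: int = 0,
    exclude: frozenset | set = frozenset(),
) -> MergeProposal | None:
    """Draw a uniformly random eligible merge pair not in ``exclude``.

    Returns None when every eligible pair has been excluded (exhausted).
    ``exclude`` holds ``frozenset({a, b})`` keys of already-tried pairs.
    """
    pairs = [
        p for p in _eligible_pairs(system, phase, parity)
        if frozenset(p) not in exclude
    ]
    if not pairs:
        return None
    a, b = pairs[int(rng.integers(len(pairs)))]
    ta, tb = system.tiles[a], system.tiles[b]
    idents = tuple(
        (ta.glues[s], tb.glues[s])
        for s in SIDES
        if ta.glues[s] is not None and tb.glues[s] is not None
    )
    return MergeProposal(tile_a=a, tile_b=b, glue_identifications=idents)


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def apply_merge(system: TileSystem, proposal: MergeProposal) -> TileSystem:
    """Apply a merge, propagating glue identifications system-wide.

    Glue labels are unified with union–find; identifying ``g`` with ``h``
    also identifies ``g*`` with ``h*``.  After substitution, tiles with
    identical four-glue signatures are canonicalised into one tile type and
    layouts are rewritten.  Raises :class:`MergeError` if the unification
    would force a glue to equal its own complement, or if two locations of a
    single layout would collapse onto one tile type.
    """
    ta = system.tiles[proposal.tile_a]
    tb = system.tiles[proposal.tile_b]
    if ta.null_sides() != tb.null_sides():
        raise MergeError("tiles have null glues on different sides")

    uf = _UnionFind()
    for label in system.glue_alphabet:
        uf.find(label)
    queue = list(proposal.glue_identifications)
    while queue:
        g, h = queue.pop()
        if uf.union(g, h):
            queue.append((complement(g), complement(h)))
    for label in system.glue_alphabet:
        if uf.find(label) == uf.find(complement(label)):
            raise MergeError(
                f"unifying {proposal.tile_a} with {proposal.tile_b} forces "
                f"glue {label!r} to equal its own complement"
            )

    # canonical label per class, complement-consistent: base labels win
    classes: dict[str, list[str]] = {}
    for label in system.glue_alphabet:
        classes.setdefault(uf.find(label), []).append(label)
    rep: dict[str, str] = {}
    for root, members in classes.items():
        if root in rep:
            continue
        comp_root = uf.find(complement(members[0]))
        pool = members + classes[comp_root]
        bases = sorted(
            (m for m in pool if not m.endswith("*")),
            key=lambda s: (len(s), s),
        )
        r = bases[0]
        base_root = uf.find(r)
        for m in classes[base_root]:
            rep[m] = r
        for m in classes[uf.find(r + "*")]:
            rep[m] = r + "*"

    def remap(g: str | None) -> str | None:
        return None if g is None else rep[g]

    renamed_tiles: dict[str, Tile] = {}
    by_signature: dict[tuple, str] = {}
    name_map: dict[str, str] = {}
    for name in sorted(system.tiles):
        tile = system.tiles[name]
        new = Tile(name, {s: remap(tile.glues[s]) for s in SIDES})
        canon = by_signature.get(new.signature)
        if canon is None:
            by_signature[new.signature] = name
            renamed_tiles[name] = new
            name_map[name] = name
        else:
            name_map[name] = canon

    new_layouts = []
    for layout in system.layouts:
        occ = {loc: name_map[t] for loc, t in layout.occupancy.items()}
        try:
            new_layouts.append(ShapeLayout(layout.name, layout.rows, layout.cols, occ))
        except TilesetError as exc:
            raise MergeError(
                f"merge collapses two locations within layout {layout.name!r}: {exc}"
            ) from exc

    alphabet = {rep[g] for g in system.glue_alphabet}
    return TileSystem(tiles=renamed_tiles, glue_alphabet=alphabet, layouts=new_layouts)


def _glue_index(system: TileSystem) -> dict[tuple[str, str], set[str]]:
    """(side, label) -> tile names presenting that non-null glue on that side."""
    index: dict[tuple[str, str], set[str]] = {}
    for tile in system.tiles.values():
        for s in SIDES:
            g = tile.glues[s]
            if g is not None:
                index.setdefault((s, g), set()).add(tile.name)
    return index


def _required_labels(
    system: TileSystem, layout: ShapeLayout, loc: tuple[int, int]
) -> dict[str, str]:
    """side -> glue label a tile at ``loc`` must present to bond the correct
    neighbour on that side (non-null constraints only)."""
    req: dict[str, str] = {}
    for s in SIDES:
        nb = layout.neighbor(loc, s)
        if nb in layout.occupancy:
            g_nb = system.tiles[layout.occupancy[nb]].glues[OPPOSITE[s]]
            if g_nb is not None:
                req[s] = complement(g_nb)
    return req


def _match_counts(
    system: TileSystem,
    layout: ShapeLayout,
    loc: tuple[int, int],
    index: dict[tuple[str, str], set[str]],
) -> dict[str, list[str]]:
    """tile name -> sides on which it bonds the correct neighbours of ``loc``."""
    matches: dict[str, list[str]] = {}
    for s, label in _required_labels(system, layout, loc).items():
        for name in index.get((s, label), ()):
            matches.setdefault(name, []).append(s)
    return matches


def check_self_healing(
    system: TileSystem, first_only: bool = False
) -> CriterionReport:
    """PASS iff at every location, every wrong tile bonds at most one correct
    neighbour (so only the correct tile can attach by >= 2 bonds)."""
    index = _glue_index(system)
    witnesses: list[SelfHealingWitness] = []
    for layout in system.layouts:
        for loc in layout.occupancy:
            correct = layout.occupancy[loc]
            for name, sides in _match_counts(system, layout, loc, index).items():
                if name != correct and len(sides) >= 2:
                    witnesses.append(
                        SelfHealingWitness(layout.name, loc, name, tuple(sides))
                    )
                    if first_only:
                        return CriterionReport(False, tuple(witnesses))
    return CriterionReport(not witnesses, tuple(witnesses))


def check_second_order(
    system: TileSystem, first_only: bool = False
) -> CriterionReport:
    """PASS iff no 1-bond wrong attachment enables a further 2-bond wrong
    attachment in its neighbourhood.

    For every location ``l`` and wrong tile ``t`` bonding exactly one correct
    neighbour, every adjacent position ``l2`` (other than the bonded
    neighbour, including positions outside the shape) is checked: no tile
    ``t2`` other than the correct tile for ``l2`` may reach two bonds using
    the glue presented by ``t`` plus glues of correct neighbours of ``l2``.
    """
    index = _glue_index(system)
    witnesses: list[SecondOrderWitness] = []
    for layout in system.layouts:
        occ = layout.occupancy
        for loc in occ:
            correct = occ[loc]
            for t_name, sides in _match_counts(system, layout, loc, index).items():
                if t_name == correct or len(sides) != 1:
                    continue
                t = system.tiles[t_name]
                bonded_nb = layout.neighbor(loc, sides[0])
                for s in SIDES:
                    l2 = layout.neighbor(loc, s)
                    if l2 == bonded_nb:
                        continue
                    g_t = t.glues[s]
                    if g_t is None:
                        continue  # no bond to the erroneous tile possible
                    correct2 = occ.get(l2)
                    # candidate second tiles must bond t through side s
                    for t2_name in index.get((OPPOSITE[s], complement(g_t)), ()):
                        if t2_name == correct2:
                            continue
                        t2 = system.tiles[t2_name]
                        bonds = 1  # the bond to t
                        for s2 in SIDES:
                            if s2 == OPPOSITE[s]:
                                continue
                            l3 = (
                                l2[0] + SIDE_OFFSETS[s2][0],
                                l2[1] + SIDE_OFFSETS[s2][1],
                            )
                            if l3 == loc or l3 not in occ:
                                continue
                            g2 = t2.glues[s2]
                            g3 = system.tiles[occ[l3]].glues[OPPOSITE[s2]]
                            if g2 is not None and g3 == complement(g2):
                                bonds += 1
                        if bonds >= 2:
                            witnesses.append(
                                SecondOrderWitness(
                                    layout.name, loc, t_name, l2, t2_name
                                )
                            )
                            if first_only:
                                return CriterionReport(False, tuple(witnesses))
    return CriterionReport(not witnesses, tuple(witnesses))


def _merge_once(
    system: TileSystem, rng: np.random.Generator, parity: int
) -> tuple[TileSystem, MergeLog]:
    log = MergeLog(parity=parity)
    for phase in ("chequerboard", "global"):
        tried: set[frozenset] = set()
        while True:
            proposal = propose_merge(system, rng, phase, parity, exclude=tried)
            if proposal is None:
                break
            try:
                candidate = apply_merge(system, proposal)
            except MergeError as exc:
                log.rejected.append(
                    (phase, proposal.tile_a, proposal.tile_b, f"apply: {exc}")
                )
                tried.add(proposal.key)
                continue
            reason = None
            if any(validate_layout(candidate, lay) for lay in candidate.layouts):
                reason = "layout-invalid"
            elif not check_self_healing(candidate, first_only=True).ok:
                reason = "self-healing"
            elif not check_second_order(candidate, first_only=True).ok:
                reason = "second-order"
            if reason is None:
                system = candidate
                log.accepted.append((phase, proposal.tile_a, proposal.tile_b))
                log.tile_counts.append(len(system.tiles))
                log.glue_pair_counts.append(system.n_glue_pairs())
                tried = set()
            else:
                log.rejected.append((phase, proposal.tile_a, proposal.tile_b, reason))
                tried.add(proposal.key)
    return system, log


def run_merging(
    system: TileSystem,
    rng: np.random.Generator | int,
    restarts: int = 1,
    parity: int = 0,
) -> tuple[TileSystem, MergeLog]:
    """Run the stochastic merge search and return the smallest system found.

    Each restart runs the chequerboard phase to exhaustion, then the global
    phase to exhaustion, checking layout validity and both proofreading
    criteria after every proposed merge.  Across restarts the system with the
    fewest tile types wins; the winning run's :class:`MergeLog` is returned
    with it.  Reproducible for a fixed seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    best: tuple[TileSystem, MergeLog] | None = None
    for _ in range(restarts):
        merged, log = _merge_once(system.copy(), rng, parity)
        if best is None or len(merged.tiles) < len(best[0].tiles):
            best = (merged, log)
    return best
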