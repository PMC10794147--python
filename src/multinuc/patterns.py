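"""Concentration-pattern construction: images, the pixel-to-tile map and flags.

A grayscale image becomes a concentration pattern in three steps: it is
rescaled to a fixed pixel grid (area-average downsampling), discretised to
ten grayscale levels ``p = k/9`` with a *fixed* level histogram shared by all
images (rank-based assignment), and each pixel's level is mapped to the
concentration of the tile assigned to that pixel position by the pixel-to-tile
map ``theta`` through the exponential formula

    c_i = c_base * exp(3 * p_n * ln 3)      (c_base = 16.67 nM)

which makes the ten level concentrations geometric from 16.67 nM (p = 0) to
450 nM (p = 1), factor 3^(1/3) apart.  Tiles not assigned to any pixel stay
at the base concentration; *reserved* tiles (fluorophore/quencher label
locations, which must not vary in concentration) are drawn from that
unassigned pool and are never assigned to pixels.

The standard histogram is a package constant: the integer level histogram
closest to a geometric level profile subject to 900 pixels totalling a 60 nM
mean tile concentration.  It is part of the package's file contract, frozen
and versioned here.

A *flag* is the simpler hand-designed pattern family: all tiles at a base
concentration except the shared-sublattice (chequerboard) tiles inside one
k-by-k window of one shape, which are enhanced; tiles unique to a shape are
never enhanced (avoiding a direct thermodynamic bias toward that shape).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .energetics import ConcentrationPattern
from .tileset import ShapeLayout, TileSystem

__all__ = [
    "N_LEVELS",
    "BASE_CONC_NM",
    "STANDARD_HISTOGRAM",
    "STANDARD_IMAGE_SIZE",
    "level_concentrations",
    "standard_histogram",
    "PixelImage",
    "preprocess_image",
    "load_image",
    "random_level_image",
    "ThetaMap",
    "image_to_concentrations",
    "FlagPattern",
    "make_flag",
]

N_LEVELS = 10
BASE_CONC_NM = 16.67
STANDARD_IMAGE_SIZE = 30

#: Frozen level histogram for 900-pixel standardized images (level 0..9).
#: Sums to 900; mean tile concentration 60 nM to the nearest nM.
STANDARD_HISTOGRAM = (254, 185, 135, 99, 72, 53, 38, 28, 21, 15)


def level_concentrations(base_nm: float = BASE_CONC_NM) -> np.ndarray:
    """The ten level concentrations ``base * exp(3 * (k/9) * ln 3)`` in nM."""
    p = np.arange(N_LEVELS) / (N_LEVELS - 1)
    return base_nm * np.exp(3.0 * p * math.log(3.0))


def standard_histogram() -> tuple[int, ...]:
    """Pixel counts per grayscale level for standardized 30x30 images."""
    return STANDARD_HISTOGRAM


@dataclass(frozen=True)
class PixelImage:
    """A discretised grayscale image: integer levels 0..9 per pixel."""

    levels: np.ndarray  # int array, shape (rows, cols), values in [0, 9]

    def __post_init__(self) -> None:
        arr = np.asarray(self.levels, dtype=int)
        if arr.ndim != 2:
            raise ValueError("levels must be a 2-D array")
        if arr.min() < 0 or arr.max() >= N_LEVELS:
            raise ValueError(f"levels must lie in [0, {N_LEVELS - 1}]")
        object.__setattr__(self, "levels", arr)

    @property
    def p(self) -> np.ndarray:
        """Grayscale values ``p = k/9`` in [0, 1]."""
        return self.levels / (N_LEVELS - 1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.levels.shape  # type: ignore[return-value]

    def histogram(self) -> tuple[int, ...]:
        return tuple(
            int(n) for n in np.bincount(self.levels.ravel(), minlength=N_LEVELS)
        )

    def has_standard_histogram(self) -> bool:
        return self.histogram() == STANDARD_HISTOGRAM


def _overlap_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic box-overlap matrix for exact area-average resampling."""
    w = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for i in range(n_out):
        lo, hi = i * scale, (i + 1) * scale
        j0, j1 = int(math.floor(lo)), int(math.ceil(hi))
        for j in range(j0, min(j1, n_in)):
            w[i, j] = min(hi, j + 1) - max(lo, j)
    return w / w.sum(axis=1, keepdims=True)


def preprocess_image(
    raw: np.ndarray | Sequence[Sequence[float]],
    size: int = STANDARD_IMAGE_SIZE,
    histogram: Sequence[int] | None = None,
) -> PixelImage:
    """Standardize a grayscale image: rescale, discretise, equalise histogram.

    The input (any 2-D grayscale array, higher = brighter) is area-average
    resampled to ``size x size``, then pixels are ranked by intensity (ties
    broken by row-major scan order) and assigned levels so that the level
    histogram equals the standard histogram exactly.  The output is invariant
    under monotone intensity transforms of the input, and standardized images
    pass through unchanged.
    """
    img = np.asarray(raw, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if histogram is None:
        histogram = _scaled_histogram(size * size)
    if sum(histogram) != size * size:
        raise ValueError("histogram must sum to the number of pixels")
    if img.shape != (size, size):
        img = _overlap_matrix(size, img.shape[0]) @ img @ _overlap_matrix(
            size, img.shape[1]
        ).T
    flat = img.ravel()
    order = np.argsort(flat, kind="stable")  # ties resolved by scan order
    levels_flat = np.empty(flat.size, dtype=int)
    bounds = np.cumsum((0,) + tuple(histogram))
    for k in range(N_LEVELS):
        levels_flat[order[bounds[k] : bounds[k + 1]]] = k
    return PixelImage(levels_flat.reshape(size, size))


def _scaled_histogram(n_pixels: int) -> tuple[int, ...]:
    """Standard histogram rescaled to ``n_pixels`` (largest-remainder rounding)."""
    if n_pixels == sum(STANDARD_HISTOGRAM):
        return STANDARD_HISTOGRAM
    target = np.array(STANDARD_HISTOGRAM, dtype=float)
    target = target * n_pixels / target.sum()
    counts = np.floor(target).astype(int)
    rem = target - counts
    for k in np.argsort(-rem)[: n_pixels - counts.sum()]:
        counts[k] += 1
    return tuple(counts)


def load_image(path: str) -> np.ndarray:
    """Load a PNG/PGM/etc. image as a 2-D float grayscale array."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=float)


def random_level_image(
    shape: tuple[int, int],
    rng: np.random.Generator,
    histogram: Sequence[int] | None = None,
) -> PixelImage:
    """Random image with the (rescaled) standard level histogram."""
    n = shape[0] * shape[1]
    hist = _scaled_histogram(n) if histogram is None else tuple(histogram)
    if sum(hist) != n:
        raise ValueError("histogram must sum to the number of pixels")
    levels = np.repeat(np.arange(N_LEVELS), hist)
    return PixelImage(rng.permutation(levels).reshape(shape))


class ThetaMap:
    """Injective assignment of pixel positions to tile names.

    Tiles not assigned to any pixel form the *unassigned* pool and keep the
    base concentration; reserved tiles (fluorophore label locations) must
    stay in that pool.
    """

    def __init__(
        self,
        assignments: Mapping[tuple[int, int], str],
        tile_names: Iterable[str],
        reserved: Iterable[str] = (),
    ):
        self.assignments = dict(assignments)
        self.tile_names = frozenset(tile_names)
        self.reserved = frozenset(reserved)
        assigned = list(self.assignments.values())
        if len(set(assigned)) != len(assigned):
            raise ValueError("theta must be injective (one tile per pixel)")
        unknown = set(assigned) - self.tile_names
        if unknown:
            raise ValueError(f"theta assigns unknown tiles {sorted(unknown)}")
        bad = set(assigned) & self.reserved
        if bad:
            raise ValueError(f"reserved tiles assigned to pixels: {sorted(bad)}")
        if not self.reserved <= self.tile_names:
            raise ValueError("reserved tiles must belong to the system")
        self.unassigned = tuple(sorted(self.tile_names - set(assigned)))

    def __getitem__(self, pixel: tuple[int, int]) -> str:
        return self.assignments[pixel]

    def __len__(self) -> int:
        return len(self.assignments)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ThetaMap)
            and self.assignments == other.assignments
            and self.tile_names == other.tile_names
            and self.reserved == other.reserved
        )

    @staticmethod
    def random(
        tile_names: Iterable[str],
        image_shape: tuple[int, int],
        rng: np.random.Generator,
        reserved: Iterable[str] = (),
    ) -> "ThetaMap":
        """Uniformly random injective assignment avoiding reserved tiles."""
        tile_names = sorted(set(tile_names))
        reserved = frozenset(reserved)
        pool = [t for t in tile_names if t not in reserved]
        pixels = [
            (r, c) for r in range(image_shape[0]) for c in range(image_shape[1])
        ]
        if len(pool) < len(pixels):
            raise ValueError(
                f"{len(pixels)} pixels but only {len(pool)} assignable tiles"
            )
        chosen = rng.permutation(len(pool))[: len(pixels)]
        return ThetaMap(
            {pix: pool[i] for pix, i in zip(pixels, chosen)}, tile_names, reserved
        )

    # -- moves used by hill climbing (each returns a new, still-valid map) --

    def swap_pixels(self, p1: tuple[int, int], p2: tuple[int, int]) -> "ThetaMap":
        a = dict(self.assignments)
        a[p1], a[p2] = a[p2], a[p1]
        return ThetaMap(a, self.tile_names, self.reserved)

    def swap_with_unassigned(self, pixel: tuple[int, int], tile: str) -> "ThetaMap":
        if tile not in self.unassigned or tile in self.reserved:
            raise ValueError(f"{tile!r} is not an assignable unassigned tile")
        a = dict(self.assignments)
        a[pixel] = tile
        return ThetaMap(a, self.tile_names, self.reserved)

    # -- I/O: CSV with columns pixel_row,pixel_col,tile --

    def to_csv(self, fp: IO[str] | str) -> None:
        rows = [(r, c, t) for (r, c), t in sorted(self.assignments.items())]
        pd.DataFrame(rows, columns=["pixel_row", "pixel_col", "tile"]).to_csv(
            fp, index=False
        )

    @staticmethod
    def from_csv(
        fp: IO[str] | str, tile_names: Iterable[str], reserved: Iterable[str] = ()
    ) -> "ThetaMap":
        df = pd.read_csv(fp)
        a = {
            (int(r), int(c)): t
            for r, c, t in zip(df["pixel_row"], df["pixel_col"], df["tile"])
        }
        return ThetaMap(a, tile_names, reserved)


def image_to_concentrations(
    image: PixelImage,
    theta: ThetaMap,
    system: TileSystem,
    base_nm: float = BASE_CONC_NM,
) -> ConcentrationPattern:
    """Convert an image to tile concentrations through the map theta.

    ``c_theta(n) = base * exp(3 * p_n * ln 3)`` nM; every tile of the system
    not assigned to a pixel (including all reserved tiles) is set to the base
    concentration, so the resulting pattern covers the system exactly.
    """
    if set(theta.tile_names) != set(system.tiles):
        raise ValueError("theta was built for a different tile set")
    conc = {t: base_nm for t in system.tiles}
    p = image.p
    for (r, c), tile in theta.assignments.items():
        if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
            raise ValueError(f"theta pixel {(r, c)} outside the image")
        if tile in theta.reserved:
            raise ValueError(f"pixel {(r, c)} mapped to reserved tile {tile!r}")
        conc[tile] = base_nm * math.exp(3.0 * p[r, c] * math.log(3.0))
    return ConcentrationPattern(conc)


@dataclass(frozen=True)
class FlagPattern:
    """A chequerboard flag: enhanced shared tiles in one window of one shape."""

    shape: str
    center: tuple[int, int]
    window: int
    base_nm: float
    enhanced_nm: float
    enhanced_tiles: frozenset[str]

    def to_pattern(self, system: TileSystem) -> ConcentrationPattern:
        return ConcentrationPattern(
            {
                t: self.enhanced_nm if t in self.enhanced_tiles else self.base_nm
                for t in system.tiles
            }
        )


def _shared_parity(system: TileSystem, layout: ShapeLayout, default: int) -> int:
    """Chequerboard parity of the shared-tile sublattice within a layout.

    Read from the system's sharing structure: the parity class holding more
    multi-layout tiles.  Falls back to ``default`` on a tie.
    """
    shared_names = {
        name
        for name in system.tiles
        if sum(name in lay.tile_names() for lay in system.layouts) >= 2
    }
    counts = [0, 0]
    for (r, c), name in layout.occupancy.items():
        if name in shared_names:
            counts[(r + c) % 2] += 1
    if counts[0] == counts[1]:
        return default
    return int(counts[1] > counts[0])


def make_flag(
    system: TileSystem,
    shape: str,
    center: tuple[int, int],
    base_nm: float = 50.0,
    enhanced_nm: float = 880.0,
    window: int = 5,
) -> FlagPattern:
    """Build a flag pattern: enhanced chequerboard tiles in one window.

    The ``window x window`` block centred at ``center`` must lie fully inside
    the shape.  Tiles at the shared-sublattice parity within the window are
    enhanced, except tiles unique to this shape, which are never enhanced.
    """
    layout = system.layout(shape)
    r0 = center[0] - window // 2
    c0 = center[1] - window // 2
    cells = [
        (r, c) for r in range(r0, r0 + window) for c in range(c0, c0 + window)
    ]
    missing = [cell for cell in cells if cell not in layout.occupancy]
    if missing:
        raise ValueError(
            f"{window}x{window} window at {center} extends outside shape "
            f"{shape!r} (first empty cell {missing[0]})"
        )
    parity = _shared_parity(system, layout, default=(r0 + c0) % 2)
    multiplicity = {
        name: sum(name in lay.tile_names() for lay in system.layouts)
        for name in layout.tile_names()
    }
    enhanced = {
        layout.occupancy[(r, c)]
        for (r, c) in cells
        if (r + c) % 2 == parity and multiplicity[layout.occupancy[(r, c)]] >= 2
    }
    if not enhanced:
        raise ValueError(f"window at {center} in {shape!r} contains no shared tiles")
    return FlagPattern(
        shape=shape,
        center=center,
        window=window,
        base_nm=base_nm,
        enhanced_nm=enhanced_nm,
        enhanced_tiles=frozenset(enhanced),
    )
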