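"""Free-energy model for partial tile assemblies.

The free energy of a partial assembly ``A`` with ``B`` internal bonds is

    G(A) = sum_{i in A} G_mc^i  -  B * G_se  -  alpha        (units of RT)

where ``G_mc^i = alpha - ln(c_i / u0)`` is the chemical potential
(translational entropy) of tile ``i`` at free concentration ``c_i``, ``G_se``
is the stabilisation per matched glue bond, and ``alpha`` is an offset fixed
by the choice of reference concentration ``u0``.  All logs are natural.

``alpha`` cancels in every free-energy *difference* at fixed assembly size and
in the monomer free energy ``G = -ln(c/u0)``; only such differences and the
rate ratios built from them matter downstream, so the defaults ``u0 = 1 M``,
``alpha = 0`` are a pure convention.

Optionally ``G_se`` can be derived from a per-bond enthalpy and entropy,
``G_se(T) = (-dH + T*dS) / (R*T)`` at absolute temperature ``T``, which makes
every temperature-dependent quantity in the package consistent with a single
two-parameter bond model.  The default thermodynamic parameters give a domain
free energy of about -9 kcal/mol at 53 C, a typical design target for 10-11 nt
SST binding domains near their growth temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping

import pandas as pd

from .tileset import SIDES, SIDE_OFFSETS, ShapeLayout, TilesetError

__all__ = [
    "GAS_CONSTANT_KCAL",
    "EnergyParams",
    "ConcentrationPattern",
    "AssemblyState",
    "chemical_potential",
    "bond_count",
    "assembly_free_energy",
    "attachment_delta_g",
]

#: Molar gas constant in kcal / (mol K).
GAS_CONSTANT_KCAL = 1.98720425864083e-3

#: nanomolar in units of molar
_NM = 1e-9


@dataclass(frozen=True)
class EnergyParams:
    """Energetic parameters of the assembly model.

    Parameters
    ----------
    g_se
        Bond energy per matched glue pair, in RT; positive = stabilising.
    alpha
        Reference offset (RT), set by the choice of ``u0``; cancels in all
        differences used downstream.
    u0
        Reference concentration in molar.
    dh, ds
        Optional per-bond enthalpy (kcal/mol) and entropy (kcal/mol/K).  When
        both are set, :meth:`at_temperature` recomputes ``g_se`` from them.
    """

    g_se: float = 10.5
    alpha: float = 0.0
    u0: float = 1.0
    dh: float | None = None
    ds: float | None = None

    def __post_init__(self) -> None:
        if self.g_se <= 0:
            raise ValueError("g_se must be positive (stabilising)")
        if self.u0 <= 0:
            raise ValueError("u0 must be positive")

    @staticmethod
    def from_bond_thermo(
        dh: float = -80.0,
        dg_target: float = -9.0,
        t_target_c: float = 53.0,
        alpha: float = 0.0,
        u0: float = 1.0,
    ) -> "EnergyParams":
        """Build temperature-dependent parameters from a bond free-energy target.

        ``ds`` is chosen so the per-bond standard free energy equals
        ``dg_target`` (kcal/mol) at ``t_target_c`` given enthalpy ``dh``.
        """
        t_k = t_target_c + 273.15
        ds = (dh - dg_target) / t_k
        params = EnergyParams(g_se=1.0, alpha=alpha, u0=u0, dh=dh, ds=ds)
        return params.at_temperature(t_target_c)

    def g_se_at(self, t_celsius: float) -> float:
        """``G_se`` in RT at the given temperature, from the dH/dS bond model."""
        if self.dh is None or self.ds is None:
            raise ValueError("temperature dependence requires dh and ds")
        t_k = t_celsius + 273.15
        return (-self.dh + t_k * self.ds) / (GAS_CONSTANT_KCAL * t_k)

    def at_temperature(self, t_celsius: float) -> "EnergyParams":
        """Copy of these parameters with ``g_se`` evaluated at ``t_celsius``."""
        return replace(self, g_se=self.g_se_at(t_celsius))


class ConcentrationPattern:
    """Mapping tile name -> free concentration in nM (all strictly positive)."""

    def __init__(self, conc_nm: Mapping[str, float]):
        bad = {t: c for t, c in conc_nm.items() if not c > 0}
        if bad:
            raise ValueError(f"non-positive concentrations: {bad}")
        self._conc = dict(conc_nm)

    def __getitem__(self, tile: str) -> float:
        try:
            return self._conc[tile]
        except KeyError:
            raise KeyError(f"tile {tile!r} has no concentration") from None

    def __contains__(self, tile: str) -> bool:
        return tile in self._conc

    def __len__(self) -> int:
        return len(self._conc)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ConcentrationPattern) and self._conc == other._conc

    def items(self) -> Iterable[tuple[str, float]]:
        return self._conc.items()

    def tiles(self) -> Iterable[str]:
        return self._conc.keys()

    def scaled(self, factor: float) -> "ConcentrationPattern":
        return ConcentrationPattern({t: c * factor for t, c in self._conc.items()})

    def updated(self, changes: Mapping[str, float]) -> "ConcentrationPattern":
        merged = dict(self._conc)
        merged.update(changes)
        return ConcentrationPattern(merged)

    @staticmethod
    def uniform(tiles: Iterable[str], conc_nm: float) -> "ConcentrationPattern":
        return ConcentrationPattern({t: conc_nm for t in tiles})

    @staticmethod
    def from_csv(fp: IO[str] | str) -> "ConcentrationPattern":
        """Read a two-column CSV with header ``tile,conc_nM``."""
        df = pd.read_csv(fp)
        if not {"tile", "conc_nM"} <= set(df.columns):
            raise ValueError("concentration CSV needs columns tile,conc_nM")
        return ConcentrationPattern(dict(zip(df["tile"], df["conc_nM"].astype(float))))

    def to_csv(self, fp: IO[str] | str) -> None:
        df = pd.DataFrame(sorted(self._conc.items()), columns=["tile", "conc_nM"])
        df.to_csv(fp, index=False)


@dataclass(frozen=True)
class AssemblyState:
    """A connected partial assembly: a subset of a layout's occupied locations."""

    layout: ShapeLayout
    locations: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.locations:
            raise ValueError("assembly state must be non-empty")
        extra = self.locations - set(self.layout.occupancy)
        if extra:
            raise ValueError(f"locations {sorted(extra)} not occupied in layout")
        if not self._connected():
            raise ValueError("assembly state must be 4-connected")

    def _connected(self) -> bool:
        locs = set(self.locations)
        stack = [next(iter(locs))]
        seen = {stack[0]}
        while stack:
            r, c = stack.pop()
            for dr, dc in SIDE_OFFSETS.values():
                nb = (r + dr, c + dc)
                if nb in locs and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(locs)

    def __len__(self) -> int:
        return len(self.locations)

    def tile_names(self) -> list[str]:
        return [self.layout.occupancy[loc] for loc in sorted(self.locations)]

    def frontier(self) -> set[tuple[int, int]]:
        """Empty layout locations adjacent to the state."""
        out = set()
        for r, c in self.locations:
            for dr, dc in SIDE_OFFSETS.values():
                nb = (r + dr, c + dc)
                if nb in self.layout.occupancy and nb not in self.locations:
                    out.add(nb)
        return out


def chemical_potential(
    tile: str, pattern: ConcentrationPattern, params: EnergyParams
) -> float:
    """``G_mc = alpha - ln(c_i / u0)`` in RT (concentration given in nM)."""
    c_molar = pattern[tile] * _NM
    return params.alpha - math.log(c_molar / params.u0)


def bond_count(state: AssemblyState) -> int:
    """Number of internal bonds: adjacent occupied pairs, each counted once."""
    b = 0
    for r, c in state.locations:
        if (r, c + 1) in state.locations:
            b += 1
        if (r + 1, c) in state.locations:
            b += 1
    return b


def assembly_free_energy(
    state: AssemblyState, pattern: ConcentrationPattern, params: EnergyParams
) -> float:
    """``G(A) = sum_i G_mc^i - B*G_se - alpha`` in RT."""
    g = -params.alpha
    for name in state.tile_names():
        g += chemical_potential(name, pattern, params)
    g -= bond_count(state) * params.g_se
    return g


def attachment_delta_g(
    state: AssemblyState,
    location: tuple[int, int],
    pattern: ConcentrationPattern,
    params: EnergyParams,
) -> float:
    """Free-energy change of attaching the layout's tile at ``location``.

    ``dG = G_mc(tile) - b*G_se`` with ``b`` the bonds formed to the current
    state; attachment is favourable iff ``dG < 0``.  Equals
    ``G(state + tile) - G(state)``.
    """
    if location in state.locations:
        raise ValueError(f"location {location} already occupied")
    if location not in state.layout.occupancy:
        raise ValueError(f"location {location} not part of the layout")
    r, c = location
    b = sum(
        (r + dr, c + dc) in state.locations for dr, dc in SIDE_OFFSETS.values()
    )
    if b == 0:
        raise ValueError(f"location {location} not adjacent to the state")
    name = state.layout.occupancy[location]
    return chemical_potential(name, pattern, params) - b * params.g_se
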