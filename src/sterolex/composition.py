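"""Liposome recipes, assay mixtures and accessible-lipid accounting.

A liposome recipe is a total lipid concentration plus mole fractions of its
component species.  A soluble protein only sees part of a doped lipid: a
fast-flipping sterol such as DHE equilibrates across the bilayer and is
fully accessible, whereas a phosphoinositide or PS stays in the leaflet it
was deposited in, so only the outer half (fraction 0.5) can be reached.
Accessible concentrations are what every downstream assay conversion and
kinetic equation works with.

Units: concentrations in μM, volumes in μL, compositions as mole fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

__all__ = [
    "LipidSpecies",
    "LiposomeComposition",
    "ProteinStock",
    "AssayMix",
    "accessible_concentration",
    "final_mix_concentrations",
    "lipid_to_protein_ratio",
    "STEROL_ACCESSIBLE_FRACTION",
    "OUTER_LEAFLET_FRACTION",
    "TOTAL_LIPID_KEY",
]

#: Fast-flipping sterols (DHE, cholesterol) redistribute across both leaflets.
STEROL_ACCESSIBLE_FRACTION = 1.0
#: Non-flipping lipids (PIPs, PS, headgroup-labelled PEs) stay where deposited.
OUTER_LEAFLET_FRACTION = 0.5
#: Pseudo-species key used for the summed lipid concentration of a mixture.
TOTAL_LIPID_KEY = "total_lipid"

_ROLES = ("structural", "fret_probe", "cargo", "doped_pip")


@dataclass(frozen=True)
class LipidSpecies:
    """One lipid species and the fraction of it a soluble protein can reach.

    Parameters
    ----------
    name:
        Identifier, e.g. ``"DHE"``, ``"PI34P2"``, ``"DNS-PE"``, ``"DOPC"``.
    accessible_fraction:
        Fraction of the doped amount exposed to solution, in ``(0, 1]``.
        1.0 for fast-flipping sterols; 0.5 for outer-leaflet-restricted
        lipids.
    role:
        Tag: ``structural``, ``fret_probe``, ``cargo`` or ``doped_pip``.
    """

    name: str
    accessible_fraction: float = 1.0
    role: str = "structural"

    def __post_init__(self) -> None:
        if not (0.0 < self.accessible_fraction <= 1.0):
            raise ValueError(
                f"accessible_fraction must be in (0, 1], got "
                f"{self.accessible_fraction} for {self.name!r}"
            )
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {_ROLES}")


@dataclass(frozen=True)
class LiposomeComposition:
    """A liposome population: total lipid concentration plus mole fractions.

    Mole fractions must sum to 1 within 1e-9.  Use :meth:`from_doping` to
    specify only the doped species as mole percent and let the structural
    DOPC/DOPE (2:1) filler absorb the remainder.
    """

    total_lipid_conc: float  # μM
    components: tuple  # of (LipidSpecies, mole_fraction)

    def __post_init__(self) -> None:
        if self.total_lipid_conc < 0:
            raise ValueError("total_lipid_conc must be >= 0")
        object.__setattr__(self, "components", tuple(self.components))
        total = 0.0
        seen = set()
        for species, frac in self.components:
            if not (0.0 <= frac <= 1.0):
                raise ValueError(
                    f"mole fraction of {species.name!r} out of [0, 1]: {frac}"
                )
            if species.name in seen:
                raise ValueError(f"duplicate species {species.name!r}")
            seen.add(species.name)
            total += frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mole fractions sum to {total}, expected 1 within 1e-9")

    @classmethod
    def from_doping(
        cls,
        total_lipid_uM: float,
        doped: Sequence[tuple[LipidSpecies, float]] = (),
        filler: Sequence[tuple[str, float]] = (("DOPC", 2.0), ("DOPE", 1.0)),
    ) -> "LiposomeComposition":
        """Build a composition from doped mole percents plus structural filler.

        ``doped`` lists (species, mole_percent); the filler lipids split the
        remaining mole fraction in the given ratio (DOPC/DOPE 2:1 by default).
        """
        doped_frac = sum(pct for _, pct in doped) / 100.0
        if doped_frac > 1.0 + 1e-12:
            raise ValueError(f"doped mole percents exceed 100%: {100 * doped_frac}")
        remainder = max(0.0, 1.0 - doped_frac)
        ratio_total = sum(w for _, w in filler)
        components = [(sp, pct / 100.0) for sp, pct in doped]
        for fname, w in filler:
            components.append(
                (LipidSpecies(fname, role="structural"), remainder * w / ratio_total)
            )
        return cls(total_lipid_uM, tuple(components))

    def mole_fraction(self, species: str) -> float:
        for sp, frac in self.components:
            if sp.name == species:
                return frac
        raise KeyError(f"species {species!r} not in composition")

    def species(self, name: str) -> LipidSpecies:
        for sp, _ in self.components:
            if sp.name == name:
                return sp
        raise KeyError(f"species {name!r} not in composition")

    def concentrations(self) -> dict[str, float]:
        """Total (not accessible) μM of every species, plus the lipid sum."""
        out = {sp.name: self.total_lipid_conc * frac for sp, frac in self.components}
        out[TOTAL_LIPID_KEY] = self.total_lipid_conc
        return out


def accessible_concentration(comp: LiposomeComposition, species: str) -> float:
    """Accessible concentration (μM) of a doped species.

    ``total_lipid_conc × mole_fraction × accessible_fraction``.  For the
    standard assay mixtures this reproduces the bench numbers: 200 μM total
    with 5% DHE gives 10 μM accessible DHE; 200 μM with 4% of an
    outer-leaflet phosphoinositide gives 4 μM.

    Raises
    ------
    KeyError
        If ``species`` is not part of the composition.
    """
    sp = comp.species(species)
    return comp.total_lipid_conc * comp.mole_fraction(species) * sp.accessible_fraction


@dataclass(frozen=True)
class ProteinStock:
    """A non-lipid stock (protein or plain buffer) added to an assay mix."""

    name: str
    conc: float = 0.0  # μM

    def concentrations(self) -> dict[str, float]:
        return {self.name: self.conc} if self.conc else {}


Stock = Union[LiposomeComposition, ProteinStock]


@dataclass(frozen=True)
class AssayMix:
    """An ordered series of additions to a cuvette.

    Each addition is a stock (liposome composition or protein/buffer stock)
    with the volume pipetted.  Final concentrations are volume-weighted
    averages of the stock concentrations.
    """

    additions: tuple  # of (Stock, volume_uL)
    temperature: float = 25.0  # °C

    def __post_init__(self) -> None:
        object.__setattr__(self, "additions", tuple(self.additions))
        for _, vol in self.additions:
            if vol <= 0:
                raise ValueError(f"addition volumes must be > 0, got {vol}")

    @property
    def total_volume(self) -> float:
        return sum(vol for _, vol in self.additions)


def final_mix_concentrations(mix: AssayMix) -> dict[str, float]:
    """Per-species final concentrations (μM) of an assay mixture.

    Each species: Σ(stock_conc × volume) / Σ(volume) over additions.  Moles
    are conserved: final conc × final volume equals the summed stock
    contributions per species.
    """
    total_vol = mix.total_volume
    if total_vol <= 0:
        raise ValueError("total mix volume must be > 0")
    moles: dict[str, float] = {}
    for stock, vol in mix.additions:
        for name, conc in stock.concentrations().items():
            moles[name] = moles.get(name, 0.0) + conc * vol
    return {name: m / total_vol for name, m in moles.items()}


def lipid_to_protein_ratio(accessible_lipid: float, protein: float) -> float:
    """Molar ratio of accessible doped lipid to protein (dimensionless)."""
    if protein <= 0:
        raise ValueError(f"protein concentration must be > 0, got {protein}")
    return accessible_lipid / protein
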