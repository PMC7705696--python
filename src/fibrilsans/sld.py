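"""Neutron scattering-length densities (SLD) and contrasts.

Small-angle scattering intensity is proportional to the squared
difference in scattering length density between phases.  Wood SANS
contrast variation rests on the fact that PEG, cellulose and lignin all
sit close together in SLD when equilibrated in D2O, so PEG-filled pores
become nearly invisible while the small D2O-filled spaces around the
microfibril bundles light up.  This module computes those SLDs from
composition and mass density using a bundled coherent-scattering-length
table, with mean-field H/D exchange of labile hydrogens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

from .nuclear_data import N_AVOGADRO, atomic_mass, coherent_length

__all__ = [
    "Material",
    "SLDValue",
    "compute_sld",
    "exchange_adjusted_sld",
    "contrast",
    "preset_material",
    "preset_names",
]


@dataclass(frozen=True)
class Material:
    """A homogeneous phase defined by stoichiometry and mass density.

    Parameters
    ----------
    name : str
        Free-form label.
    formula : dict
        Element/isotope symbol -> stoichiometric count per formula unit.
        Counts may be fractional (mean-field isotope mixtures).
    mass_density : float
        Bulk density in g/cm^3; must be positive.
    n_exchangeable_H : float
        Labile hydrogens per formula unit that exchange with the solvent
        (hydroxyl/amine protons).  ``0 <= n_exchangeable_H <= H count``.
    """

    name: str
    formula: dict[str, float]
    mass_density: float
    n_exchangeable_H: float = 0.0

    def __post_init__(self) -> None:
        if not self.formula:
            raise ValueError(f"material {self.name!r}: empty formula")
        for sym, count in self.formula.items():
            if count < 0:
                raise ValueError(
                    f"material {self.name!r}: negative count for {sym!r}"
                )
        if self.mass_density <= 0:
            raise ValueError(
                f"material {self.name!r}: mass_density must be > 0, "
                f"got {self.mass_density}"
            )
        n_h = self.formula.get("H", 0.0)
        if not 0 <= self.n_exchangeable_H <= n_h:
            raise ValueError(
                f"material {self.name!r}: n_exchangeable_H="
                f"{self.n_exchangeable_H} outside [0, H count={n_h}]"
            )

    @property
    def molar_mass(self) -> float:
        """Formula mass in g/mol."""
        return sum(n * atomic_mass(sym) for sym, n in self.formula.items())

    @property
    def molecular_volume(self) -> float:
        """Volume per formula unit in cubic ångström."""
        # g/mol / (g/cm3 * 1/mol) = cm3; 1 cm3 = 1e24 A^3
        return self.molar_mass / (self.mass_density * N_AVOGADRO) * 1e24


@dataclass(frozen=True)
class SLDValue:
    """A neutron scattering-length density in Å^-2 with its breakdown.

    ``components`` maps each symbol to its contribution n_i * b_i / V
    (Å^-2), summing to ``rho``.
    """

    rho: float
    components: dict[str, float] = field(default_factory=dict)

    @property
    def rho_e6(self) -> float:
        """SLD expressed in the conventional 1e-6 Å^-2 unit."""
        return self.rho * 1e6


def compute_sld(material: Material) -> SLDValue:
    """Scattering length density rho = sum(n_i b_i) / V_molecule.

    b_i are bound coherent scattering lengths (fm = 1e-5 Å) from the
    bundled table; the molecular volume follows from molar mass and
    density.  Deterministic; raises ``KeyError`` naming any unknown
    symbol and ``ValueError`` for invalid materials (via ``Material``).

    Examples
    --------
    >>> d2o = Material("D2O", {"D": 2, "O": 1}, 1.105)
    >>> round(compute_sld(d2o).rho_e6, 2)
    6.36
    """
    volume = material.molecular_volume  # A^3
    components = {
        sym: n * coherent_length(sym) * 1e-5 / volume
        for sym, n in material.formula.items()
    }
    return SLDValue(rho=sum(components.values()), components=components)


def exchange_adjusted_sld(
    material: Material, solvent_D_fraction: float
) -> SLDValue:
    """SLD after mean-field H/D exchange of the labile hydrogens.

    A fraction ``solvent_D_fraction`` of the ``n_exchangeable_H``
    hydrogens is replaced by deuterium as fractional stoichiometry
    (SLD is linear in b, so the mean-field composition gives the exact
    ensemble-average SLD).  Molar volume is kept at the protonated
    value: deuteration changes mass but not molecular packing.
    """
    if not 0 <= solvent_D_fraction <= 1:
        raise ValueError(
            f"solvent_D_fraction must lie in [0, 1], got {solvent_D_fraction}"
        )
    n_exchanged = material.n_exchangeable_H * solvent_D_fraction
    if n_exchanged == 0:
        return compute_sld(material)
    formula = dict(material.formula)
    formula["H"] = formula.get("H", 0.0) - n_exchanged
    formula["D"] = formula.get("D", 0.0) + n_exchanged
    volume = material.molecular_volume  # protonated packing volume
    components = {
        sym: n * coherent_length(sym) * 1e-5 / volume
        for sym, n in formula.items()
        if n != 0
    }
    return SLDValue(rho=sum(components.values()), components=components)


def contrast(a: SLDValue, b: SLDValue) -> float:
    """Scattering contrast (rho_a - rho_b)^2 in Å^-4.

    Symmetric in its arguments and exactly zero for equal SLDs; the
    scattered intensity of a two-phase system scales with this factor.
    """
    return (a.rho - b.rho) ** 2


def _load_presets() -> dict[str, dict]:
    text = (
        resources.files("fibrilsans") / "data" / "materials.yaml"
    ).read_text()
    return yaml.safe_load(text)


def preset_names() -> list[str]:
    """Names of the bundled preset materials."""
    return sorted(_load_presets())


def preset_material(name: str) -> Material:
    """Return a bundled preset (cellulose, lignin, peg, d2o, h2o).

    Densities and formulas are documented approximations for the wet
    cell-wall phases (see the bundled ``materials.yaml``), not claimed
    reproductions of any particular literature table.
    """
    presets = _load_presets()
    try:
        entry = presets[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        ) from None
    return Material(
        name=name,
        formula={str(k): float(v) for k, v in entry["formula"].items()},
        mass_density=float(entry["mass_density"]),
        n_exchangeable_H=float(entry.get("n_exchangeable_H", 0)),
    )
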