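"""Static nuclear data for neutron scattering-length-density calculations.

Bound coherent scattering lengths ``b_coh`` (fm) are the standard Sears
tabulation for natural-abundance elements, plus the isotopes D and T that
matter for H/D contrast variation.  Atomic masses are in unified atomic
mass units (g/mol per formula count).  The table is bundled so that SLD
computation needs no network access and is reproducible bit-for-bit.
"""

from __future__ import annotations

# symbol -> (b_coh in fm, atomic mass in g/mol)
# Sears, Neutron News 3 (1992) values for natural-abundance elements;
# D and T are the specific isotopes.
NUCLEAR_TABLE: dict[str, tuple[float, float]] = {
    "H": (-3.7390, 1.008),
    "D": (6.671, 2.014),
    "T": (4.792, 3.016),
    "C": (6.6460, 12.011),
    "N": (9.36, 14.007),
    "O": (5.803, 15.999),
    "F": (5.654, 18.998),
    "Na": (3.63, 22.990),
    "Mg": (5.375, 24.305),
    "Si": (4.1491, 28.085),
    "P": (5.13, 30.974),
    "S": (2.847, 32.06),
    "Cl": (9.5770, 35.45),
    "K": (3.67, 39.098),
    "Ca": (4.70, 40.078),
    "Fe": (9.45, 55.845),
    "Cu": (7.718, 63.546),
    "Zn": (5.680, 65.38),
    "Br": (6.795, 79.904),
    "I": (5.28, 126.904),
}

#: Avogadro's number, mol^-1
N_AVOGADRO = 6.02214076e23


def coherent_length(symbol: str) -> float:
    """Bound coherent scattering length of *symbol* in fm.

    Raises
    ------
    KeyError
        If the element/isotope symbol is not in the bundled table; the
        message names the offending symbol.
    """
    try:
        return NUCLEAR_TABLE[symbol][0]
    except KeyError:
        raise KeyError(
            f"unknown element/isotope symbol {symbol!r}; known symbols: "
            f"{sorted(NUCLEAR_TABLE)}"
        ) from None


def atomic_mass(symbol: str) -> float:
    """Atomic mass of *symbol* in g/mol."""
    try:
        return NUCLEAR_TABLE[symbol][1]
    except KeyError:
        raise KeyError(
            f"unknown element/isotope symbol {symbol!r}; known symbols: "
            f"{sorted(NUCLEAR_TABLE)}"
        ) from None
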