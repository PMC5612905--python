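"""Static periodic data: standard atomic weights, monoisotopic masses,
and MDL default valences.

The tables are shipped with the package so that formula and mass
computation need no runtime toolkit.  Atomic weights follow the IUPAC
standard values in use when MDL-era connection tables were current
(interval notations resolved to their conventional single values);
monoisotopic masses are those of the most abundant isotope.
"""

from .errors import UnknownElementError

# element -> standard atomic weight (g/mol)
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.00794, "He": 4.002602,
    "Li": 6.941, "Be": 9.012182, "B": 10.811, "C": 12.0107,
    "N": 14.0067, "O": 15.9994, "F": 18.9984032, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.3050, "Al": 26.9815386, "Si": 28.0855,
    "P": 30.973762, "S": 32.065, "Cl": 35.453, "Ar": 39.948,
    "K": 39.0983, "Ca": 40.078, "Ti": 47.867, "Cr": 51.9961,
    "Mn": 54.938045, "Fe": 55.845, "Co": 58.933195, "Ni": 58.6934,
    "Cu": 63.546, "Zn": 65.38, "As": 74.92160, "Se": 78.96,
    "Br": 79.904, "Pd": 106.42, "Ag": 107.8682, "Sn": 118.710,
    "I": 126.90447, "Pt": 195.084, "Au": 196.966569, "Hg": 200.59,
}

# element -> mass of the most abundant isotope (Da)
MONOISOTOPIC_MASSES: dict[str, float] = {
    "H": 1.0078250319, "He": 4.0026032497,
    "Li": 7.0160040, "Be": 9.0121821, "B": 11.0093055, "C": 12.0,
    "N": 14.0030740052, "O": 15.9949146221, "F": 18.9984032, "Ne": 19.9924401759,
    "Na": 22.98976928, "Mg": 23.98504170, "Al": 26.98153853, "Si": 27.97692653,
    "P": 30.97376163, "S": 31.97207100, "Cl": 34.96885268, "Ar": 39.9623831237,
    "K": 38.96370668, "Ca": 39.96259098, "Ti": 47.9479463, "Cr": 51.9405075,
    "Mn": 54.9380451, "Fe": 55.9349375, "Co": 58.9331950, "Ni": 57.9353429,
    "Cu": 62.9295975, "Zn": 63.9291422, "As": 74.9215965, "Se": 79.9165213,
    "Br": 78.9183371, "Pd": 105.903486, "Ag": 106.905097, "Sn": 119.9021947,
    "I": 126.904473, "Pt": 194.9647911, "Au": 196.9665687, "Hg": 201.970643,
}

# MDL default valences used for implicit-hydrogen accounting.
# Elements not listed default to 0 (no implicit hydrogens).
DEFAULT_VALENCES: dict[str, int] = {
    "H": 1, "B": 3, "C": 4, "N": 3, "O": 2,
    "F": 1, "Si": 4, "P": 3, "S": 2, "Cl": 1,
    "Br": 1, "I": 1,
}

KNOWN_ELEMENTS = frozenset(ATOMIC_WEIGHTS)


def atomic_weight(symbol: str) -> float:
    try:
        return ATOMIC_WEIGHTS[symbol]
    except KeyError:
        raise UnknownElementError(f"unknown element symbol {symbol!r}") from None


def monoisotopic_mass(symbol: str) -> float:
    try:
        return MONOISOTOPIC_MASSES[symbol]
    except KeyError:
        raise UnknownElementError(f"unknown element symbol {symbol!r}") from None


def default_valence(symbol: str) -> int:
    if symbol not in KNOWN_ELEMENTS:
        raise UnknownElementError(f"unknown element symbol {symbol!r}")
    return DEFAULT_VALENCES.get(symbol, 0)
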