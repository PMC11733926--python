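"""Embedded elemental property table.

Used by the element-fraction and element-property-statistic descriptor
blocks so that no external database is needed at run time. Properties:
melting point (K), IUPAC group number, period, atomic mass (u) and
Pauling electronegativity, covering the elements that occur in drug-like
organic chemistry plus common salts/metals seen in public property tables.
"""

from __future__ import annotations

# symbol -> (melting point K, group number, period, atomic mass, electronegativity)
ELEMENT_PROPERTIES: dict[str, tuple[float, float, float, float, float]] = {
    "H": (13.99, 1, 1, 1.008, 2.20),
    "B": (2349.0, 13, 2, 10.811, 2.04),
    "C": (3915.0, 14, 2, 12.011, 2.55),
    "N": (63.15, 15, 2, 14.007, 3.04),
    "O": (54.36, 16, 2, 15.999, 3.44),
    "F": (53.48, 17, 2, 18.998, 3.98),
    "Na": (370.94, 1, 3, 22.990, 0.93),
    "Mg": (923.0, 2, 3, 24.305, 1.31),
    "Al": (933.47, 13, 3, 26.982, 1.61),
    "Si": (1687.0, 14, 3, 28.085, 1.90),
    "P": (317.30, 15, 3, 30.974, 2.19),
    "S": (388.36, 16, 3, 32.060, 2.58),
    "Cl": (171.60, 17, 3, 35.450, 3.16),
    "K": (336.70, 1, 4, 39.098, 0.82),
    "Ca": (1115.0, 2, 4, 40.078, 1.00),
    "Fe": (1811.0, 8, 4, 55.845, 1.83),
    "Cu": (1357.77, 11, 4, 63.546, 1.90),
    "Zn": (692.68, 12, 4, 65.380, 1.65),
    "As": (1090.0, 15, 4, 74.922, 2.18),
    "Se": (494.0, 16, 4, 78.971, 2.55),
    "Br": (265.80, 17, 4, 79.904, 2.96),
    "Sn": (505.08, 14, 5, 118.710, 1.96),
    "I": (386.85, 17, 5, 126.904, 2.66),
}

PROPERTY_NAMES = (
    "melting point",
    "group number",
    "period",
    "atomic mass",
    "electronegativity",
)

STAT_NAMES = ("mean", "std", "min", "max", "range")

# Symbols for the element-fraction block (ElemNet-style composition vector).
ELEMENT_FRACTION_SYMBOLS: tuple[str, ...] = (
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U",
)


def property_value(symbol: str, prop: str) -> float | None:
    """Return an elemental property value, or None if the element is unknown."""
    try:
        return ELEMENT_PROPERTIES[symbol][PROPERTY_NAMES.index(prop)]
    except KeyError:
        return None
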