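"""Periodic-table lookups: symbols, nuclear charges, standard atomic masses.

Covers Z = 1..86, which spans every element occurring in organic and
biomolecular trajectory datasets. Masses are standard atomic weights in u.
"""

from __future__ import annotations

SYMBOLS: tuple[str, ...] = (
    "H", "He",
    "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
    "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr",
    "Rb", "Sr", "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd",
    "In", "Sn", "Sb", "Te", "I", "Xe",
    "Cs", "Ba", "La", "Ce", "Pr", "Nd", "Pm", "Sm", "Eu", "Gd", "Tb", "Dy",
    "Ho", "Er", "Tm", "Yb", "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt",
    "Au", "Hg", "Tl", "Pb", "Bi", "Po", "At", "Rn",
)

ATOMIC_NUMBER: dict[str, int] = {s: z for z, s in enumerate(SYMBOLS, start=1)}

# Standard atomic weights (u); radioactive elements use the most stable isotope.
MASSES: tuple[float, ...] = (
    1.008, 4.0026,
    6.94, 9.0122, 10.81, 12.011, 14.007, 15.999, 18.998, 20.180,
    22.990, 24.305, 26.982, 28.085, 30.974, 32.06, 35.45, 39.948,
    39.098, 40.078, 44.956, 47.867, 50.942, 51.996, 54.938, 55.845,
    58.933, 58.693, 63.546, 65.38,
    69.723, 72.630, 74.922, 78.971, 79.904, 83.798,
    85.468, 87.62, 88.906, 91.224, 92.906, 95.95, 97.0, 101.07, 102.91,
    106.42, 107.87, 112.41,
    114.82, 118.71, 121.76, 127.60, 126.90, 131.29,
    132.91, 137.33, 138.91, 140.12, 140.91, 144.24, 145.0, 150.36, 151.96,
    157.25, 158.93, 162.50, 164.93, 167.26, 168.93, 173.05, 174.97, 178.49,
    180.95, 183.84, 186.21, 190.23, 192.22, 195.08,
    196.97, 200.59, 204.38, 207.2, 208.98, 209.0, 210.0, 222.0,
)


def symbol_of(z: int) -> str:
    """Chemical symbol for nuclear charge ``z``."""
    if not 1 <= z <= len(SYMBOLS):
        raise ValueError(f"unsupported atomic number {z}")
    return SYMBOLS[z - 1]


def number_of(symbol: str) -> int:
    """Nuclear charge for chemical symbol ``symbol``."""
    try:
        return ATOMIC_NUMBER[symbol]
    except KeyError:
        raise ValueError(f"unknown element symbol {symbol!r}") from None


def mass_of(symbol: str) -> float:
    """Standard atomic mass (u) for chemical symbol ``symbol``."""
    return MASSES[number_of(symbol) - 1]
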