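"""Standard atomic weights (amu) for the elements this package touches.

Values are the IUPAC 2021 conventional atomic weights, sufficient for the
organic chromophores, water and nucleic-acid environments the pipeline
targets plus a spread of heavier elements for generality.
"""

from __future__ import annotations

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "He": 4.002602,
    "Li": 6.94, "Be": 9.0121831, "B": 10.81, "C": 12.011,
    "N": 14.007, "O": 15.999, "F": 18.998403163, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.305, "Al": 26.9815385, "Si": 28.085,
    "P": 30.973761998, "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.0983, "Ca": 40.078, "Fe": 55.845, "Cu": 63.546,
    "Zn": 65.38, "Br": 79.904, "I": 126.90447,
}


def mass_of(symbol: str) -> float:
    """Atomic mass in amu for an element symbol (case-normalized).

    Raises
    ------
    KeyError
        If the symbol is not in the bundled table; the message names it.
    """
    key = symbol.strip().capitalize() if len(symbol) > 1 else symbol.strip().upper()
    # single letters stay upper; two-letter symbols capitalize first only
    if key not in ATOMIC_MASSES:
        raise KeyError(f"unknown element symbol: {symbol!r}")
    return ATOMIC_MASSES[key]
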