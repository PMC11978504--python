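"""Chemical element lookups: symbol <-> atomic number, periodic group/period.

Group is reported on the 1..18 IUPAC scale with the f-block (lanthanides and
actinides) assigned to a dedicated bin 0; period is 1..7.
"""

from __future__ import annotations

_SYMBOLS = [
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es", "Fm",
    "Md", "No", "Lr", "Rf", "Db", "Sg", "Bh", "Hs", "Mt", "Ds",
    "Rg", "Cn", "Nh", "Fl", "Mc", "Lv", "Ts", "Og",
]

SYMBOL_TO_NUMBER = {s.upper(): i + 1 for i, s in enumerate(_SYMBOLS)}
NUMBER_TO_SYMBOL = {i + 1: s for i, s in enumerate(_SYMBOLS)}

MAX_ATOMIC_NUMBER = len(_SYMBOLS)

# Elements commonly seen as free metal ions in structures.
METAL_SYMBOLS = {
    "LI", "NA", "K", "RB", "CS", "BE", "MG", "CA", "SR", "BA",
    "AL", "GA", "IN", "TL", "SN", "PB",
    "SC", "TI", "V", "CR", "MN", "FE", "CO", "NI", "CU", "ZN",
    "Y", "ZR", "NB", "MO", "TC", "RU", "RH", "PD", "AG", "CD",
    "LA", "HF", "TA", "W", "RE", "OS", "IR", "PT", "AU", "HG",
}

_PERIOD_STARTS = (1, 3, 11, 19, 37, 55, 87)


def atomic_number(symbol: str) -> int:
    """Atomic number for an element symbol (case-insensitive).

    Raises ``KeyError`` listing the symbol when it cannot be mapped.
    """
    key = symbol.strip().upper()
    if key not in SYMBOL_TO_NUMBER:
        raise KeyError(f"unmappable element symbol: {symbol!r}")
    return SYMBOL_TO_NUMBER[key]


def chemical_period(z: int) -> int:
    if not 1 <= z <= MAX_ATOMIC_NUMBER:
        raise ValueError(f"atomic number out of range: {z}")
    period = 1
    for p, start in enumerate(_PERIOD_STARTS, start=1):
        if z >= start:
            period = p
    return period


def chemical_group(z: int) -> int:
    """IUPAC group 1..18; lanthanides/actinides return 0 (f-block bin)."""
    period = chemical_period(z)
    if z == 1:
        return 1
    if z == 2:
        return 18
    start = _PERIOD_STARTS[period - 1]
    pos = z - start + 1  # 1-based position within the period
    if period in (2, 3):
        return pos if pos <= 2 else pos + 10
    if period in (4, 5):
        return pos
    # periods 6 and 7 contain the 14-element f-block after group 2
    if pos <= 2:
        return pos
    if pos <= 17:  # La..Yb / Ac..No and the group-3 slot (Lu/Lr)
        if pos <= 16:
            return 0
        return 3
    return pos - 14


def infer_element_from_atom_name(atom_name: str) -> int:
    """Best-effort element from a PDB atom name when the element column is absent."""
    name = atom_name.strip()
    if not name:
        raise KeyError("empty atom name")
    # two-letter attempt first (e.g. FE, ZN, CL), then one-letter
    stripped = "".join(c for c in name if c.isalpha())
    for cand in (stripped[:2], stripped[:1]):
        if cand.upper() in SYMBOL_TO_NUMBER:
            return SYMBOL_TO_NUMBER[cand.upper()]
    raise KeyError(f"cannot infer element for atom name: {atom_name!r}")
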