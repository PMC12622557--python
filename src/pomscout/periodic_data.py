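"""Static element tables: covalent radii and atomic masses.

Covalent radii (Å) follow Cordero et al.'s single-bond compilation; masses
are CIAAW standard atomic weights. Both are shipped as pinned constants so
bond perception and centers of mass are reproducible independent of any
external dependency version.
"""

from __future__ import annotations

# single-bond covalent radii, Å
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "B": 0.84,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "Na": 1.66,
    "Mg": 1.41,
    "Si": 1.11,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "K": 2.03,
    "Ca": 1.76,
    "Fe": 1.32,
    "Cu": 1.32,
    "Zn": 1.22,
    "Se": 1.20,
    "Mo": 1.54,
    "W": 1.62,
}

# standard atomic weights, u
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Fe": 55.845,
    "Cu": 63.546,
    "Zn": 65.38,
    "Se": 78.971,
    "Mo": 95.95,
    "W": 183.84,
}

# elements treated as metal centers: contacts between two of these are not
# perceived as covalent bonds (metal-metal distances in oxo clusters fall
# below the summed-radius cutoff without being bonds)
METALS: frozenset[str] = frozenset({"Na", "Mg", "K", "Ca", "Fe", "Cu", "Zn", "Mo", "W"})


def covalent_radius(symbol: str) -> float:
    try:
        return COVALENT_RADII[symbol]
    except KeyError:
        raise KeyError(f"no tabulated covalent radius for element {symbol!r}") from None


def atomic_mass(symbol: str) -> float:
    try:
        return ATOMIC_MASSES[symbol]
    except KeyError:
        raise KeyError(f"no tabulated atomic mass for element {symbol!r}") from None


# all IUPAC element symbols, for input validation
ELEMENT_SYMBOLS: frozenset[str] = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)


def normalize_symbol(raw: str) -> str:
    """Case-normalize an element symbol ('MO' -> 'Mo', 'h' -> 'H')."""
    s = raw.strip()
    if not s or not s.isalpha():
        raise ValueError(f"invalid element symbol {raw!r}")
    s = s[0].upper() + s[1:].lower()
    if s not in ELEMENT_SYMBOLS:
        raise ValueError(f"unknown element symbol {raw!r}")
    return s
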