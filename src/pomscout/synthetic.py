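"""Generators for every input the pipeline needs.

No external structure database is required: amino-acid templates are built
from ideal internal coordinates (textbook bond lengths and angles) via a
Z-matrix, peptide fragments are assembled residue-by-residue in an extended
backbone conformation, and analytic planted-well landscapes provide exactly
solvable stand-in potential-energy surfaces with known ground truth.

All generators are pure functions of their arguments (spec + seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import (
    AdsorptionSystem,
    Molecule,
    Torsion,
    detect_rotatable_torsions,
    perceive_bonds,
)

__all__ = [
    "SUPPORTED_RESIDUES",
    "ResidueTemplate",
    "PeptideSpec",
    "PlantedLandscape",
    "build_residue",
    "build_peptide",
    "make_landscape",
    "make_adsorption_fixture",
    "make_conformer_space",
]


# ---------------------------------------------------------------------------
# Z-matrix construction (NeRF placement)
# ---------------------------------------------------------------------------

# ideal internal coordinates, Å / degrees
_R = {
    "C-C": 1.53,
    "C-N": 1.47,
    "C=O": 1.22,
    "C-OH": 1.36,
    "O-H": 0.97,
    "N-H": 1.01,
    "C-H": 1.09,
    "C-S": 1.81,
    "C-N_amide": 1.33,
}
_TET = 109.5


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta: float, phi: float) -> np.ndarray:
    """Place atom d bonded to c with angle d-c-b = theta and dihedral
    d-c-b-a = phi (degrees). Natural-extension reference frame placement."""
    th, ph = np.radians(theta), np.radians(phi)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-r * np.cos(th), r * np.sin(th) * np.cos(ph), r * np.sin(th) * np.sin(ph)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


ZRow = tuple  # (name, element, parent, r, angle_ref, angle, dihedral_ref, dihedral)


def _zmat_to_molecule(rows: list[ZRow]) -> tuple[Molecule, dict[str, int]]:
    """Realize a named Z-matrix; bonds come from the parent links."""
    index: dict[str, int] = {}
    coords = np.zeros((len(rows), 3))
    elements: list[str] = []
    bonds: list[tuple[int, int]] = []
    for k, row in enumerate(rows):
        name, element = row[0], row[1]
        if name in index:
            raise ValueError(f"duplicate atom name {name!r}")
        index[name] = k
        elements.append(element)
        if k == 0:
            coords[k] = (0.0, 0.0, 0.0)
        elif k == 1:
            _, _, parent, r = row[:4]
            coords[k] = coords[index[parent]] + np.array([r, 0.0, 0.0])
            bonds.append((index[parent], k))
        elif k == 2:
            _, _, parent, r, aref, angle = row[:6]
            c, b = coords[index[parent]], coords[index[aref]]
            virtual = b + np.array([0.0, 0.0, 1.0])
            coords[k] = _nerf(virtual, b, c, r, angle, 90.0)
            bonds.append((index[parent], k))
        else:
            name, element, parent, r, aref, angle, dref, dihedral = row
            coords[k] = _nerf(
                coords[index[dref]], coords[index[aref]], coords[index[parent]],
                r, angle, dihedral,
            )
            bonds.append((index[parent], k))
    mol = Molecule(elements=elements, coords=coords, bonds=bonds)
    return mol, index


def _methyl(prefix: str, c: str, b: str, a: str) -> list[ZRow]:
    """Three staggered hydrogens on a methyl carbon ``c``."""
    return [
        (f"{prefix}1", "H", c, _R["C-H"], b, _TET, a, 60.0),
        (f"{prefix}2", "H", c, _R["C-H"], b, _TET, a, 180.0),
        (f"{prefix}3", "H", c, _R["C-H"], b, _TET, a, 300.0),
    ]


def _methylene(prefix: str, c: str, b: str, a: str) -> list[ZRow]:
    """Two hydrogens flanking an anti chain continuation at ``c``."""
    return [
        (f"{prefix}1", "H", c, _R["C-H"], b, _TET, a, 60.0),
        (f"{prefix}2", "H", c, _R["C-H"], b, _TET, a, 300.0),
    ]


def _backbone() -> list[ZRow]:
    """Neutral amino-acid backbone H2N-CHR-COOH; side chain attaches at CA
    with dihedral 120° about CA-C relative to the carbonyl O."""
    rows: list[ZRow] = [
        ("N", "N", None, None, None, None, None, None),
        ("CA", "C", "N", _R["C-N"]),
        ("C", "C", "CA", _R["C-C"], "N", 110.0),
        ("O", "O", "C", _R["C=O"], "CA", 121.0, "N", 0.0),
        ("OXT", "O", "C", _R["C-OH"], "CA", 113.0, "N", 180.0),
        ("HXT", "H", "OXT", _R["O-H"], "C", 106.0, "CA", 180.0),
        ("H1", "H", "N", _R["N-H"], "CA", _TET, "C", 60.0),
        ("H2", "H", "N", _R["N-H"], "CA", _TET, "C", 300.0),
        ("HA", "H", "CA", _R["C-H"], "C", _TET, "O", 240.0),
    ]
    return rows


_SLOTS = (60.0, 180.0, 300.0)


def _free_slots(*taken: float) -> list[float]:
    """Staggered dihedral slots not occupied by heavy substituents."""
    return [s for s in _SLOTS if s not in taken]


# Side-chain Z-matrix fragments, attached at CA (dihedral about CA-C
# measured against the carbonyl O, 120° opposite HA at 240°). The first
# side-chain dihedral chi1 is gauche(-) (300° against N) and deeper chain
# dihedrals are anti: the combination that keeps both the isolated residue
# and the extended peptide chain clash-free.
def _sidechain(name: str, chi1: float = 300.0) -> list[ZRow]:
    ca_attach = lambda nm, el, r: (nm, el, "CA", r, "C", _TET, "O", 120.0)
    h1, h2 = _free_slots(chi1)
    if name == "Gly":
        return [("HA2", "H", "CA", _R["C-H"], "C", _TET, "O", 120.0)]
    if name == "Ala":
        return [ca_attach("CB", "C", _R["C-C"])] + _methyl("HB", "CB", "CA", "C")
    if name == "Val":
        b1, b2 = chi1, (chi1 + 120.0) % 360.0
        (hb,) = _free_slots(b1, b2)
        return [
            ca_attach("CB", "C", _R["C-C"]),
            ("CG1", "C", "CB", _R["C-C"], "CA", 111.0, "N", b1),
            ("CG2", "C", "CB", _R["C-C"], "CA", 111.0, "N", b2),
            ("HB", "H", "CB", _R["C-H"], "CA", 108.0, "N", hb),
            *_methyl("HG1", "CG1", "CB", "CA"),
            *_methyl("HG2", "CG2", "CB", "CA"),
        ]
    if name == "Leu":
        return [
            ca_attach("CB", "C", _R["C-C"]),
            ("CG", "C", "CB", _R["C-C"], "CA", 112.0, "N", chi1),
            (f"HB1", "H", "CB", _R["C-H"], "CA", _TET, "N", h1),
            (f"HB2", "H", "CB", _R["C-H"], "CA", _TET, "N", h2),
            # anti chi2 keeps the delta methyls clear of the backbone
            ("CD1", "C", "CG", _R["C-C"], "CB", 111.0, "CA", 180.0),
            ("CD2", "C", "CG", _R["C-C"], "CB", 111.0, "CA", 300.0),
            ("HG", "H", "CG", _R["C-H"], "CB", 108.0, "CA", 60.0),
            *_methyl("HD1", "CD1", "CG", "CB"),
            *_methyl("HD2", "CD2", "CG", "CB"),
        ]
    if name == "Ile":
        b1, b2 = chi1, (chi1 + 120.0) % 360.0
        (hb,) = _free_slots(b1, b2)
        return [
            ca_attach("CB", "C", _R["C-C"]),
            ("CG1", "C", "CB", _R["C-C"], "CA", 111.0, "N", b1),
            ("CG2", "C", "CB", _R["C-C"], "CA", 111.0, "N", b2),
            ("HB", "H", "CB", _R["C-H"], "CA", 108.0, "N", hb),
            ("CD1", "C", "CG1", _R["C-C"], "CB", 112.0, "CA", 180.0),
            ("HG11", "H", "CG1", _R["C-H"], "CB", _TET, "CA", 60.0),
            ("HG12", "H", "CG1", _R["C-H"], "CB", _TET, "CA", 300.0),
            *_methyl("HG2", "CG2", "CB", "CA"),
            *_methyl("HD1", "CD1", "CG1", "CB"),
        ]
    if name == "Met":
        return [
            ca_attach("CB", "C", _R["C-C"]),
            ("CG", "C", "CB", _R["C-C"], "CA", 112.0, "N", chi1),
            (f"HB1", "H", "CB", _R["C-H"], "CA", _TET, "N", h1),
            (f"HB2", "H", "CB", _R["C-H"], "CA", _TET, "N", h2),
            ("SD", "S", "CG", _R["C-S"], "CB", 112.0, "CA", 180.0),
            ("HG1", "H", "CG", _R["C-H"], "CB", _TET, "CA", 60.0),
            ("HG2", "H", "CG", _R["C-H"], "CB", _TET, "CA", 300.0),
            ("CE", "C", "SD", _R["C-S"], "CG", 100.0, "CB", 180.0),
            *_methyl("HE", "CE", "SD", "CG"),
        ]
    if name == "Lys":
        return [
            ca_attach("CB", "C", _R["C-C"]),
            ("CG", "C", "CB", _R["C-C"], "CA", 112.0, "N", chi1),
            (f"HB1", "H", "CB", _R["C-H"], "CA", _TET, "N", h1),
            (f"HB2", "H", "CB", _R["C-H"], "CA", _TET, "N", h2),
            ("CD", "C", "CG", _R["C-C"], "CB", 112.0, "CA", 180.0),
            ("HG1", "H", "CG", _R["C-H"], "CB", _TET, "CA", 60.0),
            ("HG2", "H", "CG", _R["C-H"], "CB", _TET, "CA", 300.0),
            ("CE", "C", "CD", _R["C-C"], "CG", 112.0, "CB", 180.0),
            ("HD1", "H", "CD", _R["C-H"], "CG", _TET, "CB", 60.0),
            ("HD2", "H", "CD", _R["C-H"], "CG", _TET, "CB", 300.0),
            ("NZ", "N", "CE", _R["C-N"], "CD", 111.0, "CG", 180.0),
            ("HE1", "H", "CE", _R["C-H"], "CD", _TET, "CG", 60.0),
            ("HE2", "H", "CE", _R["C-H"], "CD", _TET, "CG", 300.0),
            ("HZ1", "H", "NZ", _R["N-H"], "CE", _TET, "CD", 60.0),
            ("HZ2", "H", "NZ", _R["N-H"], "CE", _TET, "CD", 300.0),
        ]
    raise KeyError(name)


SUPPORTED_RESIDUES = ("Gly", "Ala", "Val", "Leu", "Ile", "Met", "Lys")

# residues whose side chain is a pure alkyl chain/branch (contact-analysis
# targets: their side-chain hydrogens get tagged)
_ALKYL_SIDECHAINS = frozenset({"Ala", "Val", "Leu", "Ile", "Lys"})


@dataclass(frozen=True)
class ResidueTemplate:
    """Ideal-geometry residue: realized molecule, atom-name index, torsions."""

    name: str
    molecule: Molecule
    atom_index: dict[str, int]
    torsions: tuple[Torsion, ...]


def build_residue(name: str, tag_sidechain: bool = True) -> ResidueTemplate:
    """Build a neutral ideal-geometry amino acid with bond graph and
    rotatable-torsion list populated.

    Supported residues: Gly, Ala, Val, Leu, Ile, Met, Lys.
    """
    if name not in SUPPORTED_RESIDUES:
        raise KeyError(
            f"unsupported residue {name!r}; supported: {', '.join(SUPPORTED_RESIDUES)}"
        )
    rows = _backbone() + _sidechain(name)
    mol, index = _zmat_to_molecule(rows)
    if tag_sidechain:
        tags: list[str | None] = [None] * mol.n_atoms
        backbone_names = {r[0] for r in _backbone()}
        adj = mol.adjacency()
        for nm, k in index.items():
            if nm in backbone_names:
                tags[k] = "backbone"
            elif (
                mol.elements[k] == "H"
                and name in _ALKYL_SIDECHAINS
                and all(mol.elements[j] == "C" for j in adj[k])
            ):
                tags[k] = "sidechain-alkyl-H"
            else:
                tags[k] = "sidechain"
        mol = Molecule(
            elements=mol.elements, coords=mol.coords, bonds=mol.bonds, tags=tags
        )
    torsions = tuple(detect_rotatable_torsions(mol))
    return ResidueTemplate(name=name, molecule=mol, atom_index=index, torsions=torsions)


# ---------------------------------------------------------------------------
# Peptide fragments
# ---------------------------------------------------------------------------


# extended-strand backbone dihedrals, degrees: a perfectly flat phi=psi=180
# zigzag clashes branched side chains into the neighbouring carbonyls, so the
# fixed chain shape uses polyproline-II-like values instead
_PHI = 270.0  # phi = -90
_PSI = 170.0


@dataclass(frozen=True)
class PeptideSpec:
    """Sequence + fixed extended-strand conformation (φ=−90°, ψ=170°, ω=180°)."""

    sequence: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 2 <= len(self.sequence) <= 8:
            raise ValueError("peptide length must be between 2 and 8 residues")
        for r in self.sequence:
            if r not in SUPPORTED_RESIDUES:
                raise KeyError(f"unsupported residue {r!r}")


def build_peptide(spec: PeptideSpec) -> Molecule:
    """Assemble an extended rigid peptide chain with trans peptide bonds.

    The N-terminus carries two amine hydrogens, the C-terminus a hydroxyl;
    every build with the same spec is bit-for-bit identical. Side-chain
    hydrogens of alkyl residues are tagged ``sidechain-alkyl-H``.
    """
    rows: list[ZRow] = []
    for i, res in enumerate(spec.sequence):
        p = f"r{i}:"
        q = f"r{i-1}:"
        if i == 0:
            rows += [
                (p + "N", "N", None, None, None, None, None, None),
                (p + "CA", "C", p + "N", _R["C-N"]),
                (p + "C", "C", p + "CA", _R["C-C"], p + "N", 110.0),
                (p + "H1", "H", p + "N", _R["N-H"], p + "CA", _TET, p + "C", 60.0),
                (p + "H2", "H", p + "N", _R["N-H"], p + "CA", _TET, p + "C", 300.0),
            ]
        else:
            rows += [
                # omega = 180 (trans); beta-strand backbone phi/psi keeps the
                # side chains clear of the neighbouring carbonyls (a perfectly
                # flat 180/180 zigzag clashes for branched residues)
                (p + "N", "N", q + "C", _R["C-N_amide"], q + "CA", 116.0, q + "N", _PSI),
                (p + "H", "H", p + "N", _R["N-H"], q + "C", 119.0, q + "CA", 0.0),
                (p + "CA", "C", p + "N", _R["C-N"], q + "C", 122.0, q + "CA", 180.0),
                (p + "C", "C", p + "CA", _R["C-C"], p + "N", 110.0, q + "C", _PHI),
            ]
        o_dih = (_PSI - 180.0) if i < len(spec.sequence) - 1 else _PSI - 180.0
        if i < len(spec.sequence) - 1:
            rows.append((p + "O", "O", p + "C", _R["C=O"], p + "CA", 121.0, p + "N", o_dih))
        else:
            rows += [
                (p + "O", "O", p + "C", _R["C=O"], p + "CA", 121.0, p + "N", o_dih),
                (p + "OXT", "O", p + "C", _R["C-OH"], p + "CA", 113.0, p + "N", o_dih + 180.0),
                (p + "HXT", "H", p + "OXT", _R["O-H"], p + "C", 106.0, p + "CA", 180.0),
            ]
        rows.append((p + "HA", "H", p + "CA", _R["C-H"], p + "C", _TET, p + "O", 240.0))
        for row in _sidechain(res):
            renamed = tuple(
                p + v if isinstance(v, str) and not v.startswith("r") and k in (0, 2, 4, 6) else v
                for k, v in enumerate(row)
            )
            rows.append(renamed)
    mol, index = _zmat_to_molecule(rows)
    tags: list[str | None] = [None] * mol.n_atoms
    backbone_names = {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "HA", "HXT"}
    adj = mol.adjacency()
    for nm, k in index.items():
        i, base = nm.split(":")
        res = spec.sequence[int(i[1:])]
        if base in backbone_names:
            tags[k] = "backbone"
        elif (
            mol.elements[k] == "H"
            and res in _ALKYL_SIDECHAINS
            and all(mol.elements[j] == "C" for j in adj[k])
        ):
            tags[k] = "sidechain-alkyl-H"
        else:
            tags[k] = "sidechain"
    return Molecule(elements=mol.elements, coords=mol.coords, bonds=mol.bonds, tags=tags)


# ---------------------------------------------------------------------------
# Planted analytic landscapes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedLandscape:
    """Sum of negative Gaussian wells plus optional band-limited roughness.

    The analytic global minimum at zero roughness is the center of the
    deepest well — the exactly known ground truth for recovery tests.
    """

    dimension: int
    centers: np.ndarray  # (n_wells, dimension)
    depths: np.ndarray  # eV, > 0
    widths: np.ndarray  # same units as the coordinates
    lower: np.ndarray
    upper: np.ndarray
    periodic: np.ndarray  # bool per dimension
    roughness: float = 0.0
    seed: int = 0
    _rough_freq: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _rough_phase: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if np.any(self.depths <= 0):
            raise ValueError("well depths must be positive")
        if np.any(self.centers < self.lower) or np.any(self.centers > self.upper):
            raise ValueError("well centers must lie inside the bounds")
        if self._rough_freq is None:
            rng = np.random.default_rng(self.seed)
            n_modes = 6
            span = self.upper - self.lower
            # integer mode counts keep the roughness term periodic where the
            # dimension is periodic
            freq = rng.integers(1, 4, size=(n_modes, self.dimension)) * (
                2.0 * np.pi / span
            )
            phase = rng.uniform(0.0, 2.0 * np.pi, size=n_modes)
            object.__setattr__(self, "_rough_freq", freq)
            object.__setattr__(self, "_rough_phase", phase)

    @property
    def n_wells(self) -> int:
        return len(self.depths)

    def _delta(self, q: np.ndarray) -> np.ndarray:
        """Periodic-aware displacement of q from every center, (n_wells, dim)."""
        d = q[None, :] - self.centers
        span = self.upper - self.lower
        for k in np.flatnonzero(self.periodic):
            d[:, k] = (d[:, k] + span[k] / 2) % span[k] - span[k] / 2
        return d

    def energy(self, q: np.ndarray) -> float:
        q = np.asarray(q, dtype=float)
        if q.shape != (self.dimension,):
            raise ValueError(
                f"point has dimension {q.shape}, landscape is {self.dimension}-dimensional"
            )
        d = self._delta(q)
        r2 = (d**2).sum(axis=1)
        e = float(-(self.depths * np.exp(-r2 / (2.0 * self.widths**2))).sum())
        if self.roughness > 0:
            phases = self._rough_freq @ q + self._rough_phase
            e += float(self.roughness * np.cos(phases).mean())
        return e

    def gradient(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        d = self._delta(q)
        r2 = (d**2).sum(axis=1)
        w2 = self.widths**2
        g = (self.depths * np.exp(-r2 / (2 * w2)) / w2)[:, None] * d
        grad = g.sum(axis=0)
        if self.roughness > 0:
            phases = self._rough_freq @ q + self._rough_phase
            grad += -self.roughness * (np.sin(phases)[:, None] * self._rough_freq).mean(axis=0)
        return grad

    def global_minimum(self) -> tuple[np.ndarray, float]:
        """Deepest-well center and its energy (exact at zero roughness)."""
        k = int(np.argmax(self.depths))
        return self.centers[k].copy(), self.energy(self.centers[k])


def _auto_width(dimension: int, span: float, basin_fraction: float = 0.07) -> float:
    """Well width whose 2σ basin occupies ``basin_fraction`` of the domain.

    Keeps planted minima discoverable by quasi-random sampling at any
    dimension: a fixed absolute width would shrink the basin's volume
    fraction exponentially with dimension, leaving landscapes that no
    sampler could explore at realistic budgets. Potential-energy surfaces
    of the systems this package emulates show the same picture the other
    way around — a few broad competing basins covering a substantial part
    of the accessible search space.
    """
    from scipy.special import gamma

    ball = np.pi ** (dimension / 2.0) / gamma(dimension / 2.0 + 1.0)
    two_w = (basin_fraction * span**dimension / ball) ** (1.0 / dimension)
    return two_w / 2.0


def make_landscape(
    dimension: int,
    n_wells: int,
    seed: int,
    periodic: np.ndarray | list[bool] | None = None,
    lower: float = 0.0,
    upper: float = 10.0,
    width_range: tuple[float, float] | None = None,
    depth_range: tuple[float, float] = (0.4, 1.0),
    roughness: float = 0.0,
) -> PlantedLandscape:
    """Draw a seeded planted landscape with well-separated minima.

    Widths default to the dimension-scaled value of :func:`_auto_width`
    (±8%), so each basin stays a fixed, discoverable fraction of the domain
    volume. Centers are redrawn until all pairwise (periodic-aware)
    separations reach 3× the largest width; unsatisfiable specs raise after
    10⁴ draws. The deepest well is made unique by construction so the global
    minimum is unambiguous.
    """
    if not 1 <= dimension <= 8:
        raise ValueError("dimension must be in 1..8")
    if n_wells < 1:
        raise ValueError("need at least one well")
    rng = np.random.default_rng(seed)
    lo = np.full(dimension, float(lower))
    hi = np.full(dimension, float(upper))
    per = (
        np.zeros(dimension, dtype=bool)
        if periodic is None
        else np.asarray(periodic, dtype=bool)
    )
    if width_range is None:
        w0 = _auto_width(dimension, float(upper - lower))
        width_range = (0.95 * w0, 1.1 * w0)
    widths = rng.uniform(*width_range, size=n_wells)
    min_sep = 3.0 * widths.max()
    span = hi - lo
    for _ in range(10_000):
        centers = rng.uniform(lo + 0.05 * span, hi - 0.05 * span, size=(n_wells, dimension))
        d = centers[:, None, :] - centers[None, :, :]
        for k in np.flatnonzero(per):
            d[:, :, k] = (d[:, :, k] + span[k] / 2) % span[k] - span[k] / 2
        sep = np.sqrt((d**2).sum(axis=-1))
        np.fill_diagonal(sep, np.inf)
        if sep.min() >= min_sep:
            break
    else:
        raise RuntimeError(
            f"could not place {n_wells} wells separated by {min_sep:.2f} in 10^4 draws"
        )
    depths = np.sort(rng.uniform(*depth_range, size=n_wells))[::-1].copy()
    depths[0] = depth_range[1]  # unambiguous global minimum
    return PlantedLandscape(
        dimension=dimension,
        centers=centers,
        depths=depths,
        widths=widths,
        lower=lo,
        upper=hi,
        periodic=per,
        roughness=roughness,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Adsorption fixture
# ---------------------------------------------------------------------------


def make_adsorption_fixture(
    seed: int,
    adsorbate: str | PeptideSpec = "Gly",
    shell: tuple[float, float] = (2.0, 8.0),
):
    """Ideal Keggin cluster + adsorbate + 6-DOF pose search space.

    Returns ``(cluster, adsorbate_molecule, space)``. Translations are bounded
    by a box enclosing a shell ``shell`` Å outside the terminal-oxygen hull;
    the three rotations are periodic. Poses that land the adsorbate inside
    the cluster are legal points of the space — the sampling loop flags them
    as unphysical and clamps their energy rather than excluding them.
    """
    from .bo import Dimension, SearchSpace
    from .keggin import build_ideal_keggin

    cluster = build_ideal_keggin()
    if isinstance(adsorbate, PeptideSpec):
        mol = build_peptide(adsorbate)
    else:
        mol = build_residue(adsorbate).molecule
    hull_radius = float(
        np.linalg.norm(
            cluster.molecule.coords[cluster.terminal_oxygens], axis=1
        ).max()
    )
    r_out = hull_radius + shell[1]
    dims = [
        Dimension("x", "translation", -r_out, r_out, False),
        Dimension("y", "translation", -r_out, r_out, False),
        Dimension("z", "translation", -r_out, r_out, False),
        Dimension("h", "rotation", -180.0, 180.0, True),
        Dimension("i", "rotation", -180.0, 180.0, True),
        Dimension("j", "rotation", -180.0, 180.0, True),
    ]

    def realize(q: np.ndarray) -> AdsorptionSystem:
        from .structures import RigidPose, apply_pose

        pose = RigidPose(translation=tuple(q[:3]), rotation=tuple(q[3:6]))
        return AdsorptionSystem(
            cluster=cluster.molecule, adsorbate=apply_pose(mol, pose)
        )

    def invalid(system: AdsorptionSystem) -> bool:
        # clash, or drifted outside the interaction shell: both are poses
        # the sampler should learn to avoid, echoing the removal of
        # non-physical and beyond-interaction-distance configurations
        from .energy import detect_unphysical

        if system.inter_distances().min() > shell[1]:
            return True
        return detect_unphysical(system)[0]

    space = SearchSpace(dims=dims, realize=realize, invalid_check=invalid)
    return cluster, mol, space


def make_conformer_space(template: ResidueTemplate):
    """Torsion search space for a residue template (one periodic dimension
    per rotatable torsion)."""
    from .bo import Dimension, SearchSpace
    from .structures import set_torsions

    dims = [
        Dimension(f"d{k+1}", "torsion", -180.0, 180.0, True)
        for k in range(len(template.torsions))
    ]

    def realize(q: np.ndarray) -> Molecule:
        return set_torsions(template.molecule, list(template.torsions), list(q))

    return SearchSpace(dims=dims, realize=realize)
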