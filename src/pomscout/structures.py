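"""Molecular data model and geometry manipulation.

The :class:`Molecule` record (elements, coordinates, bond graph) is the unit
of all geometry in the package. On top of it this module provides XYZ
reading/writing, distance-based bond perception against the shipped covalent
radius table, rotatable-torsion detection and torsion driving (internal
coordinates preserved), rigid-body pose application, and the two-fragment
:class:`AdsorptionSystem` used by the adsorption studies.

Conventions
-----------
* Coordinates are in Å, angles in degrees.
* Torsion angles live in [-180, 180); driving a torsion rotates the connected
  component on the *d* side of the ``a-b-c-d`` quadruple about the b→c axis.
* Rigid poses use intrinsic z-y-x Euler angles (h, i, j): rotation about the
  fragment's center of mass followed by translation of that center of mass
  to the target point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .periodic_data import (
    METALS,
    atomic_mass,
    covalent_radius,
    normalize_symbol,
)

__all__ = [
    "Molecule",
    "Torsion",
    "RigidPose",
    "AdsorptionSystem",
    "read_xyz",
    "read_xyz_frames",
    "write_xyz",
    "read_pdb",
    "perceive_bonds",
    "connected_components",
    "detect_rotatable_torsions",
    "measure_torsion",
    "set_torsions",
    "apply_pose",
    "center_of_mass",
    "wrap_angle",
]


def wrap_angle(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle in degrees to the canonical range [-180, 180)."""
    return (np.asarray(angle) + 180.0) % 360.0 - 180.0


@dataclass
class Molecule:
    """Elements + coordinates + undirected bond graph.

    ``partial_charges`` are pass-through values (supplied externally or by a
    charge-assignment scheme); the data model never computes them. ``tags``
    carry optional per-atom role labels such as ``terminal-oxygen`` or
    ``sidechain-alkyl-H``.
    """

    elements: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int]] = field(default_factory=list)
    formal_charge: int = 0
    partial_charges: np.ndarray | None = None
    tags: list[str | None] | None = None
    comment: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.coords):
            raise ValueError(
                f"{len(self.elements)} elements but {len(self.coords)} coordinates"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        n = len(self.elements)
        seen = set()
        norm_bonds: list[tuple[int, int]] = []
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-loop bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            key = (min(i, j), max(i, j))
            if key not in seen:
                seen.add(key)
                norm_bonds.append(key)
        self.bonds = norm_bonds
        if self.partial_charges is not None:
            self.partial_charges = np.asarray(self.partial_charges, dtype=float)
            if self.partial_charges.shape != (n,):
                raise ValueError("partial_charges length mismatch")
        if self.tags is not None and len(self.tags) != n:
            raise ValueError("tags length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for a, b in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        return [sorted(x) for x in adj]

    def degree(self, i: int) -> int:
        return len(self.neighbors(i))

    def has_bond(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in set(self.bonds)

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        return replace(self, coords=np.asarray(coords, dtype=float).copy())

    def copy(self) -> "Molecule":
        return replace(
            self,
            coords=self.coords.copy(),
            bonds=list(self.bonds),
            partial_charges=None
            if self.partial_charges is None
            else self.partial_charges.copy(),
            tags=None if self.tags is None else list(self.tags),
        )

    def masses(self) -> np.ndarray:
        return np.array([atomic_mass(e) for e in self.elements])

    def formula(self) -> str:
        from collections import Counter

        counts = Counter(self.elements)
        return "".join(
            f"{el}{counts[el] if counts[el] > 1 else ''}"
            for el in sorted(counts, key=lambda e: (e != "C", e != "H", e))
        )


@dataclass(frozen=True)
class Torsion:
    """Proper dihedral a-b-c-d; the pivot is the bond (b, c).

    ``moving_set`` is the connected component containing *d* once the pivot
    bond is deleted — the atoms rotated when the torsion is driven.
    """

    atoms: tuple[int, int, int, int]
    moving_set: frozenset[int]

    @property
    def pivot(self) -> tuple[int, int]:
        return (self.atoms[1], self.atoms[2])


@dataclass(frozen=True)
class RigidPose:
    """6-DOF rigid placement: translation target (x, y, z) for the center of
    mass, and intrinsic z-y-x Euler angles (h, i, j) in degrees."""

    translation: tuple[float, float, float]
    rotation: tuple[float, float, float]

    def __post_init__(self) -> None:
        t = np.asarray(self.translation, dtype=float)
        if t.shape != (3,) or not np.all(np.isfinite(t)):
            raise ValueError("translation must be a finite 3-vector")
        object.__setattr__(self, "translation", tuple(float(v) for v in t))
        r = tuple(float(wrap_angle(a)) for a in self.rotation)
        if len(r) != 3:
            raise ValueError("rotation must be three Euler angles")
        object.__setattr__(self, "rotation", r)

    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("ZYX", self.rotation, degrees=True).as_matrix()


@dataclass
class AdsorptionSystem:
    """A rigid host cluster plus an adsorbate fragment.

    Keeps the two fragments separate so inter-fragment analytics (binding
    energy, MDC, minimal distances) have an unambiguous pair designation.
    """

    cluster: Molecule
    adsorbate: Molecule

    def combined(self) -> Molecule:
        nc = self.cluster.n_atoms
        bonds = list(self.cluster.bonds) + [
            (i + nc, j + nc) for i, j in self.adsorbate.bonds
        ]
        charges = None
        if (
            self.cluster.partial_charges is not None
            and self.adsorbate.partial_charges is not None
        ):
            charges = np.concatenate(
                [self.cluster.partial_charges, self.adsorbate.partial_charges]
            )
        tags = None
        if self.cluster.tags is not None or self.adsorbate.tags is not None:
            tags = (self.cluster.tags or [None] * nc) + (
                self.adsorbate.tags or [None] * self.adsorbate.n_atoms
            )
        return Molecule(
            elements=self.cluster.elements + self.adsorbate.elements,
            coords=np.vstack([self.cluster.coords, self.adsorbate.coords]),
            bonds=bonds,
            formal_charge=self.cluster.formal_charge + self.adsorbate.formal_charge,
            partial_charges=charges,
            tags=tags,
        )

    def inter_distances(self) -> np.ndarray:
        """Full inter-fragment distance matrix (cluster atoms × adsorbate atoms)."""
        diff = self.cluster.coords[:, None, :] - self.adsorbate.coords[None, :, :]
        return np.linalg.norm(diff, axis=-1)


# ---------------------------------------------------------------------------
# XYZ / PDB I/O
# ---------------------------------------------------------------------------


class XYZParseError(ValueError):
    pass


def _parse_frame(lines: list[str], offset: int) -> tuple[Molecule, int]:
    if not lines:
        raise XYZParseError(f"line {offset + 1}: empty XYZ content")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZParseError(
            f"line {offset + 1}: malformed atom-count line {lines[0]!r}"
        ) from None
    if len(lines) < count + 2:
        raise XYZParseError(
            f"line {offset + 1}: header declares {count} atoms but only "
            f"{max(len(lines) - 2, 0)} atom records follow"
        )
    comment = lines[1].rstrip("\n")
    elements: list[str] = []
    coords = np.empty((count, 3))
    for k in range(count):
        ln = offset + 3 + k
        parts = lines[2 + k].split()
        if len(parts) < 4:
            raise XYZParseError(f"line {ln}: expected 'element x y z', got {lines[2 + k]!r}")
        try:
            sym = normalize_symbol(parts[0])
        except ValueError:
            raise XYZParseError(f"line {ln}: unknown element symbol {parts[0]!r}") from None
        try:
            coords[k] = [float(v) for v in parts[1:4]]
        except ValueError:
            raise XYZParseError(f"line {ln}: non-numeric coordinate") from None
        elements.append(sym)
    mol = Molecule(elements=elements, coords=coords, comment=comment)
    return mol, count + 2


def read_xyz(path: str | Path) -> Molecule:
    """Read a single-frame XYZ file (Å; element symbols, not atomic numbers)."""
    lines = Path(path).read_text().splitlines()
    mol, _ = _parse_frame(lines, 0)
    return mol


def read_xyz_frames(path: str | Path) -> list[Molecule]:
    """Read a concatenated multi-frame XYZ file (structure ensembles)."""
    lines = Path(path).read_text().splitlines()
    frames: list[Molecule] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        mol, used = _parse_frame(lines[pos:], pos)
        frames.append(mol)
        pos += used
    if not frames:
        raise XYZParseError("line 1: empty XYZ content")
    return frames


def write_xyz(path: str | Path, mols: Molecule | Iterable[Molecule]) -> None:
    """Write one or more frames in XYZ format; comment lines are preserved."""
    if isinstance(mols, Molecule):
        mols = [mols]
    out = []
    for mol in mols:
        out.append(f"{mol.n_atoms}\n{mol.comment}\n")
        for el, (x, y, z) in zip(mol.elements, mol.coords):
            out.append(f"{el:<3s} {x: 18.10f} {y: 18.10f} {z: 18.10f}\n")
    Path(path).write_text("".join(out))


def read_pdb(path: str | Path) -> Molecule:
    """Minimal PDB reader: ATOM/HETATM records only; occupancy/B ignored."""
    elements: list[str] = []
    coords: list[list[float]] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            raw = line[76:78].strip() or line[12:16].strip()[0]
            elements.append(normalize_symbol(raw))
            coords.append(xyz)
        except (ValueError, IndexError):
            raise XYZParseError(f"line {ln}: malformed PDB atom record") from None
    if not elements:
        raise XYZParseError("no ATOM/HETATM records found")
    return Molecule(elements=elements, coords=np.array(coords))


# ---------------------------------------------------------------------------
# Bond perception and graph utilities
# ---------------------------------------------------------------------------


def perceive_bonds(
    mol: Molecule, scale: float = 1.2, metal_metal: bool = False
) -> Molecule:
    """Assign bonds by the summed-covalent-radius rule.

    A bond (i, j) is present iff dist(i, j) ≤ ``scale`` × (r_cov(i) + r_cov(j)).
    Contacts between two metal centers are skipped unless ``metal_metal`` is
    set: in oxo clusters metal-metal distances routinely undercut the radius
    sum without being bonds.
    """
    radii = np.array([covalent_radius(e) for e in mol.elements])
    d = np.linalg.norm(mol.coords[:, None, :] - mol.coords[None, :, :], axis=-1)
    cutoff = scale * (radii[:, None] + radii[None, :])
    bonds = []
    for i in range(mol.n_atoms):
        for j in range(i + 1, mol.n_atoms):
            if not metal_metal and mol.elements[i] in METALS and mol.elements[j] in METALS:
                continue
            if d[i, j] <= cutoff[i, j]:
                bonds.append((i, j))
    return replace(mol.copy(), bonds=bonds)


def connected_components(n_atoms: int, bonds: Sequence[tuple[int, int]]) -> list[set[int]]:
    adj: list[list[int]] = [[] for _ in range(n_atoms)]
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)
    seen = [False] * n_atoms
    comps = []
    for start in range(n_atoms):
        if seen[start]:
            continue
        stack, comp = [start], set()
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.add(v)
            for w in adj[v]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(comp)
    return comps


def _in_ring(mol: Molecule, bond: tuple[int, int]) -> bool:
    """True iff the bond lies on a cycle (endpoints stay connected without it)."""
    b, c = bond
    remaining = [x for x in mol.bonds if set(x) != {b, c}]
    for comp in connected_components(mol.n_atoms, remaining):
        if b in comp and c in comp:
            return True
    return False


def _side_component(mol: Molecule, pivot: tuple[int, int], side: int) -> set[int]:
    b, c = pivot
    remaining = [x for x in mol.bonds if set(x) != {b, c}]
    for comp in connected_components(mol.n_atoms, remaining):
        if side in comp:
            return comp
    raise AssertionError("unreachable")


def _is_methyl_rotor_end(mol: Molecule, end: int, other: int) -> bool:
    """Pivot endpoint is a carbon bonded to exactly three hydrogens + the pivot."""
    if mol.elements[end] != "C":
        return False
    nbrs = [k for k in mol.neighbors(end) if k != other]
    return len(nbrs) == 3 and all(mol.elements[k] == "H" for k in nbrs)


def detect_rotatable_torsions(mol: Molecule) -> list[Torsion]:
    """Enumerate rotatable torsions by the codified rotatable-bond rule.

    One torsion per acyclic bond, excluding (i) bonds with a degree-1
    endpoint (nothing to rotate / multiple-bond terminus) and (ii) three-fold
    methyl rotors. Reference atoms a and d are the lowest-index neighbors of
    the pivot endpoints; the list is ordered by pivot indices.
    """
    if not mol.bonds:
        return []
    torsions = []
    for b, c in sorted(mol.bonds):
        if mol.degree(b) < 2 or mol.degree(c) < 2:
            continue
        if _is_methyl_rotor_end(mol, b, c) or _is_methyl_rotor_end(mol, c, b):
            continue
        if _in_ring(mol, (b, c)):
            continue
        a = min(k for k in mol.neighbors(b) if k != c)
        d = min(k for k in mol.neighbors(c) if k != b)
        moving = frozenset(_side_component(mol, (b, c), d))
        torsions.append(Torsion(atoms=(a, b, c, d), moving_set=moving))
    return torsions


def measure_torsion(mol: Molecule, torsion: Torsion | tuple[int, int, int, int]) -> float:
    """Signed dihedral a-b-c-d in degrees, wrapped to [-180, 180)."""
    atoms = torsion.atoms if isinstance(torsion, Torsion) else torsion
    p = mol.coords[list(atoms)]
    b0 = p[0] - p[1]
    b1 = p[2] - p[1]
    b2 = p[3] - p[2]
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def set_torsions(
    mol: Molecule,
    torsions: Sequence[Torsion],
    values: Sequence[float],
) -> Molecule:
    """Drive each torsion to its target value (degrees), in list order.

    Only the moving-set atoms rotate about the pivot axis, so every bond
    length and bond angle is preserved exactly (rigid internal geometry).
    Raises if a pivot lies in a ring, where the rotation is undefined.
    """
    if len(values) != len(torsions):
        raise ValueError("values length must match torsions length")
    coords = mol.coords.copy()
    work = mol.with_coords(coords)
    for torsion, target in zip(torsions, values):
        b, c = torsion.pivot
        if not work.has_bond(b, c):
            raise ValueError(f"pivot {torsion.pivot} is not a bond of the molecule")
        if _in_ring(work, (b, c)):
            raise ValueError(f"pivot {torsion.pivot} lies in a ring; rotation undefined")
        current = measure_torsion(work, torsion)
        delta = np.radians(float(wrap_angle(target - current)))
        axis = work.coords[c] - work.coords[b]
        axis = axis / np.linalg.norm(axis)
        rot = Rotation.from_rotvec(axis * delta)
        moving = sorted(torsion.moving_set)
        origin = work.coords[c]
        coords = work.coords.copy()
        coords[moving] = rot.apply(coords[moving] - origin) + origin
        work = work.with_coords(coords)
        # sign convention check-free: rotation of the d-side about +axis by
        # delta increases the measured dihedral by delta
        achieved = measure_torsion(work, torsion)
        if abs(wrap_angle(achieved - target)) > 1e-6:
            # flip convention (should not trigger; kept as a hard guard)
            rot = Rotation.from_rotvec(-2 * axis * delta)
            coords[moving] = rot.apply(coords[moving] - origin) + origin
            work = work.with_coords(coords)
    return work


# ---------------------------------------------------------------------------
# Rigid-body placement
# ---------------------------------------------------------------------------


def center_of_mass(mol: Molecule) -> np.ndarray:
    """Mass-weighted mean position, standard atomic masses."""
    if mol.n_atoms == 0:
        raise ValueError("empty molecule has no center of mass")
    m = mol.masses()
    return (m[:, None] * mol.coords).sum(axis=0) / m.sum()


def apply_pose(mol: Molecule, pose: RigidPose, pivot: np.ndarray | None = None) -> Molecule:
    """Rotate about the center of mass, then translate the COM to the target.

    The rotation uses intrinsic z-y-x Euler angles (h, i, j) in degrees.
    An isometry on intra-molecular distances by construction.
    """
    com = center_of_mass(mol) if pivot is None else np.asarray(pivot, dtype=float)
    R = pose.matrix()
    rotated = (mol.coords - com) @ R.T
    target = np.asarray(pose.translation)
    return mol.with_coords(rotated + target)
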