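"""Ideal α-Keggin [PMo12O40]3− geometry and its terminal-oxygen framework.

The builder places a central PO4 tetrahedron inside twelve MoO6 octahedra
with exact T_d site symmetry: molybdenum atoms on cuboctahedron vertex
directions, the 24 bridging oxygens on the cuboctahedron edge midpoints,
the four µ4 oxygens on the T_d subset of body diagonals, and the twelve
terminal oxygens radially outside each Mo. The terminal oxygens therefore
span a cuboctahedron whose convex hull carries 6 quadrilateral and 8
triangular faces — the framework that hosts the adsorption sites.

Geometry constants are idealized from typical Keggin crystallography
(P–O ≈ 1.53 Å, Mo≡O terminal ≈ 1.67 Å, Mo at ≈ 3.55 Å from the center).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
from scipy.spatial import ConvexHull

from .structures import Molecule, perceive_bonds

__all__ = [
    "KegginCluster",
    "FrameworkFace",
    "build_ideal_keggin",
    "enumerate_framework_faces",
    "classify_site",
    "faces_report",
    "td_rotation_matrices",
    "KEGGIN_P_O",
    "KEGGIN_MO_RADIUS",
    "KEGGIN_MO_O_TERMINAL",
]

# documented ideal-geometry constants, Å
KEGGIN_P_O = 1.53
KEGGIN_MO_RADIUS = 3.55
KEGGIN_MO_O_TERMINAL = 1.67
KEGGIN_O_BRIDGE_RADIUS = 3.55


@dataclass
class KegginCluster:
    """The built cluster: molecule (1 P, 12 Mo, 40 O), terminal-oxygen
    indices, formal charge −3 e."""

    molecule: Molecule
    terminal_oxygens: list[int]

    def __post_init__(self) -> None:
        from collections import Counter

        counts = Counter(self.molecule.elements)
        if counts != Counter({"O": 40, "Mo": 12, "P": 1}):
            raise ValueError(f"not a PMo12O40 composition: {dict(counts)}")


@dataclass
class FrameworkFace:
    """One face of the terminal-oxygen framework polyhedron."""

    vertex_indices: tuple[int, ...]  # indices into the cluster molecule
    kind: str  # "triangle" | "quadrilateral"
    centroid: np.ndarray
    outward_normal: np.ndarray


def _cuboctahedron_directions() -> np.ndarray:
    """The 12 unit vectors toward cuboctahedron vertices: permutations of
    (±1, ±1, 0)/√2, in a fixed deterministic order."""
    dirs = []
    for perm in [(0, 1, 2), (0, 2, 1), (1, 2, 0)]:
        for s1 in (1, -1):
            for s2 in (1, -1):
                v = np.zeros(3)
                v[perm[0]], v[perm[1]] = s1, s2
                dirs.append(v / np.sqrt(2.0))
    return np.array(dirs)


def build_ideal_keggin(scale: float = KEGGIN_MO_O_TERMINAL) -> KegginCluster:
    """Build the ideal α-Keggin [PMo12O40]3− cluster.

    ``scale`` is the terminal Mo–O bond length in Å. The build has exact
    T_d site symmetry; perceived bonds give each Mo six oxygen neighbours
    (1 terminal + 4 bridging + 1 central) and each terminal oxygen exactly
    one Mo neighbour.
    """
    if scale <= 0:
        raise ValueError("Mo-O bond length must be positive")
    elements: list[str] = ["P"]
    coords: list[np.ndarray] = [np.zeros(3)]
    tags: list[str | None] = ["central-P"]

    # 4 µ4 oxygens of the central PO4 on the T_d body-diagonal subset
    tetra = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3.0)
    for d in tetra:
        elements.append("O")
        coords.append(KEGGIN_P_O * d)
        tags.append("central-oxygen")

    mo_dirs = _cuboctahedron_directions()
    for d in mo_dirs:
        elements.append("Mo")
        coords.append(KEGGIN_MO_RADIUS * d)
        tags.append("molybdenum")

    # 24 bridging oxygens on the cuboctahedron edge midpoints
    edge_dirs = []
    for i, j in combinations(range(12), 2):
        if abs(np.dot(mo_dirs[i], mo_dirs[j]) - 0.5) < 1e-9:  # adjacent vertices
            mid = mo_dirs[i] + mo_dirs[j]
            edge_dirs.append(mid / np.linalg.norm(mid))
    assert len(edge_dirs) == 24
    for d in edge_dirs:
        elements.append("O")
        coords.append(KEGGIN_O_BRIDGE_RADIUS * d)
        tags.append("bridging-oxygen")

    # 12 terminal oxygens radially outside each Mo
    terminal: list[int] = []
    for d in mo_dirs:
        terminal.append(len(elements))
        elements.append("O")
        coords.append((KEGGIN_MO_RADIUS + scale) * d)
        tags.append("terminal-oxygen")

    mol = Molecule(
        elements=elements,
        coords=np.array(coords),
        formal_charge=-3,
        tags=tags,
        comment="ideal alpha-Keggin [PMo12O40]3-",
    )
    mol = perceive_bonds(mol)
    return KegginCluster(molecule=mol, terminal_oxygens=terminal)


def td_rotation_matrices() -> list[np.ndarray]:
    """The 24 orthogonal matrices of the point group T_d.

    Realized as the signed permutation matrices (subgroup of O_h) that map
    the tetrahedral direction set {(1,1,1), (1,-1,-1), (-1,1,-1), (-1,-1,1)}
    onto itself: 12 proper rotations and 12 improper operations (S4 axes and
    mirror planes)."""
    mats = []
    tetra = {(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)}
    for perm in permutations(range(3)):
        P = np.zeros((3, 3))
        for r, c in enumerate(perm):
            P[r, c] = 1.0
        for signs in [(s1, s2, s3) for s1 in (1, -1) for s2 in (1, -1) for s3 in (1, -1)]:
            M = np.diag(signs) @ P
            image = {tuple(int(x) for x in (M @ np.array(v))) for v in tetra}
            if image == tetra:
                mats.append(M)
    assert len(mats) == 24
    return mats


def enumerate_framework_faces(
    cluster: KegginCluster, coplanar_tol: float = 1e-3
) -> list[FrameworkFace]:
    """Convex hull of the terminal oxygens with coplanar-face merging.

    Adjacent hull triangles whose dihedral is below ``coplanar_tol`` (radians)
    are merged, so the ideal build yields 6 quadrilaterals + 8 triangles.
    """
    pts = cluster.molecule.coords[cluster.terminal_oxygens]
    return _faces_of_points(pts, cluster.terminal_oxygens, coplanar_tol)


def _faces_of_points(
    pts: np.ndarray, labels: list[int], coplanar_tol: float
) -> list[FrameworkFace]:
    if len(pts) < 4:
        raise ValueError("need at least 4 points for a 3-D hull")
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # qhull degenerate input
        raise ValueError(f"degenerate hull: {exc}") from None
    centroid_all = pts.mean(axis=0)

    # union-find over coplanar adjacent simplices
    n_simplex = len(hull.simplices)
    parent = list(range(n_simplex))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    normals = hull.equations[:, :3]
    cos_tol = np.cos(coplanar_tol)
    for s, nbrs in enumerate(hull.neighbors):
        for t in nbrs:
            if np.dot(normals[s], normals[t]) >= cos_tol:
                parent[find(s)] = find(t)

    groups: dict[int, list[int]] = {}
    for s in range(n_simplex):
        groups.setdefault(find(s), []).append(s)

    faces = []
    for simplices in groups.values():
        verts = sorted({int(v) for s in simplices for v in hull.simplices[s]})
        vpts = pts[verts]
        centroid = vpts.mean(axis=0)
        normal = np.mean(normals[simplices], axis=0)
        normal /= np.linalg.norm(normal)
        if np.dot(normal, centroid - centroid_all) < 0:
            normal = -normal
        # order vertices by azimuth around the face normal
        u = vpts[0] - centroid
        u -= np.dot(u, normal) * normal
        u /= np.linalg.norm(u)
        w = np.cross(normal, u)
        ang = np.arctan2((vpts - centroid) @ w, (vpts - centroid) @ u)
        order = np.argsort(ang)
        ordered = tuple(labels[verts[k]] for k in order)
        kind = {3: "triangle", 4: "quadrilateral"}.get(len(verts), f"{len(verts)}-gon")
        faces.append(
            FrameworkFace(
                vertex_indices=ordered,
                kind=kind,
                centroid=centroid,
                outward_normal=normal,
            )
        )
    faces.sort(key=lambda f: tuple(f.vertex_indices))
    return faces


def faces_report(faces: list[FrameworkFace]) -> str:
    """Structured-text table of the framework faces: id, kind, vertex
    indices, centroid."""
    lines = ["face_id kind vertices centroid_x centroid_y centroid_z"]
    for fid, f in enumerate(faces):
        verts = ",".join(str(v) for v in f.vertex_indices)
        cx, cy, cz = f.centroid
        lines.append(f"{fid} {f.kind} {verts} {cx:.6f} {cy:.6f} {cz:.6f}")
    return "\n".join(lines) + "\n"


def classify_site(
    cluster: KegginCluster,
    point: np.ndarray,
    faces: list[FrameworkFace] | None = None,
    tie_tol: float = 1e-9,
) -> tuple[str, int]:
    """Classify an outside point against the framework faces.

    Returns ``(site_class, face_id)`` where site_class is the kind of the
    face whose outward normal best aligns with the centroid→point direction
    ("quadrilateral" | "triangle"), or "edge" when the two best alignments
    tie within ``tie_tol``. Points inside the hull are rejected.
    """
    point = np.asarray(point, dtype=float)
    if faces is None:
        faces = enumerate_framework_faces(cluster)
    pts = cluster.molecule.coords[cluster.terminal_oxygens]
    hull = ConvexHull(pts)
    # inside test against all hull half-spaces
    if np.all(hull.equations[:, :3] @ point + hull.equations[:, 3] <= 1e-9):
        raise ValueError("point lies inside the terminal-oxygen hull")
    centroid = pts.mean(axis=0)
    direction = point - centroid
    direction = direction / np.linalg.norm(direction)
    scores = np.array([np.dot(direction, f.outward_normal) for f in faces])
    best = int(np.argmax(scores))
    runner = float(np.partition(scores, -2)[-2])
    if scores[best] - runner < tie_tol:
        return "edge", best
    return faces[best].kind, best
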