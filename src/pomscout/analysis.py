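"""Per-structure and per-ensemble interaction analytics.

Implements the contact statistics used to characterize cluster–molecule
binding: the binding energy E_b = E(complex) − E(cluster) − E(molecule)
(negative = exothermic), distance-cutoff hydrogen-bond detection, minimal
inter-fragment distances, minimum distance counts (MDC: inter-fragment atom
pairs closer than a cutoff), the MDC–energy rank correlation, adsorption-site
classification against the terminal-oxygen framework, and a seeded 2-D
t-SNE embedding of sampled configurations for landscape visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.manifold import TSNE

from .structures import AdsorptionSystem, Molecule

__all__ = [
    "AnalysisConfig",
    "HBond",
    "InteractionReport",
    "binding_energy",
    "detect_hbonds",
    "mdc",
    "min_distance",
    "mdc_energy_trend",
    "embed_landscape",
    "analyze_system",
    "ensemble_report",
]

_POLAR = frozenset({"N", "O", "S"})


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis cutoffs.

    ``r_hb`` is the hydrogen-bond distance cutoff (donor-H···acceptor);
    ``mdc_cutoff`` the close-contact threshold for minimum distance counts.
    The optional donor-angle criterion is OFF by default: the distance-only
    definition is the one the contact statistics are built on.
    """

    r_hb: float = 3.0  # Å
    mdc_cutoff: float = 2.2  # Å
    donor_elements: frozenset = _POLAR
    acceptor_elements: frozenset = _POLAR
    use_angle_criterion: bool = False
    min_donor_angle: float = 120.0  # degrees, only if use_angle_criterion
    mdc_elements: frozenset | None = None  # optional element filter
    perplexity: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_hb <= 0 or self.mdc_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass(frozen=True)
class HBond:
    """One detected hydrogen bond (indices in the combined system)."""

    donor_h: int
    donor_parent: int
    acceptor: int
    distance: float
    pattern: str  # e.g. "N-H...O"
    intra: bool


@dataclass
class InteractionReport:
    """Per-structure analytics bundle.

    ``passthrough`` carries externally supplied quantum-chemical observables
    (per-atom charges, orbital gaps); the package never computes them.
    """

    e_complex: float
    e_cluster: float
    e_molecule: float
    e_b: float
    hbonds: list[HBond]
    min_distance: float
    min_distance_pair: tuple[int, int]
    mdc: int
    mdc_pairs: list[tuple[int, int]]
    site: tuple[str, int] | None = None
    passthrough: dict = field(default_factory=dict)


def binding_energy(
    e_complex: float,
    e_cluster: float,
    e_molecule: float,
    provenance: tuple[str, str, str] | None = None,
) -> float:
    """E_b = E(complex) − E(cluster) − E(molecule); negative = exothermic.

    When provenance hashes are supplied, all three energies must come from
    the same calculator — mixing backends silently would make E_b
    meaningless.
    """
    if provenance is not None and len(set(provenance)) != 1:
        raise ValueError(f"mixed calculator provenance: {provenance}")
    for v in (e_complex, e_cluster, e_molecule):
        if not np.isfinite(v):
            raise ValueError("non-finite energy input")
    return e_complex - e_cluster - e_molecule


def _donor_hydrogens(mol: Molecule, cfg: AnalysisConfig) -> list[tuple[int, int]]:
    """(H index, parent heavy-atom index) for H covalently bound to a donor."""
    out = []
    adj = mol.adjacency()
    for i, el in enumerate(mol.elements):
        if el != "H":
            continue
        for j in adj[i]:
            if mol.elements[j] in cfg.donor_elements:
                out.append((i, j))
                break
    return out


def detect_hbonds(
    system: Molecule | AdsorptionSystem, cfg: AnalysisConfig | None = None
) -> list[HBond]:
    """All (donor-H, acceptor) pairs within the distance cutoff.

    The donor H must be covalently bound to N/O/S; the acceptor is any N/O/S
    not bonded to that H. Bonds are labeled by donor-parent/acceptor element
    pattern (e.g. ``N-H...O``) and intra- vs inter-fragment.
    """
    cfg = cfg or AnalysisConfig()
    if isinstance(system, AdsorptionSystem):
        mol = system.combined()
        n_cluster = system.cluster.n_atoms
    else:
        mol = system
        n_cluster = None
    adj = mol.adjacency()
    bonds = []
    for h, parent in _donor_hydrogens(mol, cfg):
        for a, el in enumerate(mol.elements):
            if el not in cfg.acceptor_elements or a == parent or a in adj[h]:
                continue
            dist = float(np.linalg.norm(mol.coords[h] - mol.coords[a]))
            if dist >= cfg.r_hb:
                continue
            if cfg.use_angle_criterion:
                v1 = mol.coords[parent] - mol.coords[h]
                v2 = mol.coords[a] - mol.coords[h]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if angle < cfg.min_donor_angle:
                    continue
            intra = True
            if n_cluster is not None:
                intra = (h < n_cluster) == (a < n_cluster)
            bonds.append(
                HBond(
                    donor_h=h,
                    donor_parent=parent,
                    acceptor=a,
                    distance=dist,
                    pattern=f"{mol.elements[parent]}-H...{mol.elements[a]}",
                    intra=intra,
                )
            )
    bonds.sort(key=lambda b: (b.donor_h, b.acceptor))
    return bonds


def mdc(
    system: AdsorptionSystem, cfg: AnalysisConfig | None = None
) -> tuple[int, list[tuple[int, int]]]:
    """Minimum distance counts: inter-fragment atom pairs strictly below the
    cutoff, computed from the full distance matrix (never truncated).

    Returns (count, pair list) with pairs as (cluster atom, adsorbate atom).
    An optional element filter restricts which atoms are counted.
    """
    if not isinstance(system, AdsorptionSystem):
        raise TypeError("mdc requires a two-fragment AdsorptionSystem")
    cfg = cfg or AnalysisConfig()
    d = system.inter_distances()
    mask = d < cfg.mdc_cutoff
    if cfg.mdc_elements is not None:
        keep_c = np.array([e in cfg.mdc_elements for e in system.cluster.elements])
        keep_a = np.array([e in cfg.mdc_elements for e in system.adsorbate.elements])
        mask &= keep_c[:, None] & keep_a[None, :]
    pairs = [(int(i), int(j)) for i, j in np.argwhere(mask)]
    return len(pairs), pairs


def min_distance(system: AdsorptionSystem) -> tuple[float, tuple[int, int]]:
    """Minimal inter-fragment atomic distance and its achieving pair
    (lowest-index pair on exact ties)."""
    if not isinstance(system, AdsorptionSystem):
        raise TypeError("min_distance requires a two-fragment AdsorptionSystem")
    d = system.inter_distances()
    dmin = d.min()
    ties = np.argwhere(d == dmin)
    i, j = min((int(a), int(b)) for a, b in ties)
    return float(dmin), (i, j)


def mdc_energy_trend(
    reports: list[tuple[int, float]],
) -> tuple[float, float, str]:
    """Spearman rank correlation of MDC vs energy over an ensemble.

    Returns (rho, p-value, sign summary). Ties are handled by average ranks;
    a degenerate (all-identical) input reports NaN with sign 'undefined'.
    """
    if len(reports) < 3:
        raise ValueError("need at least 3 (mdc, energy) points")
    m = np.array([r[0] for r in reports], dtype=float)
    e = np.array([r[1] for r in reports], dtype=float)
    if np.all(m == m[0]) or np.all(e == e[0]):
        return float("nan"), float("nan"), "undefined"
    rho, p = spearmanr(m, e)
    sign = "negative" if rho < 0 else ("positive" if rho > 0 else "zero")
    return float(rho), float(p), sign


def embed_landscape(
    points: np.ndarray,
    energies: np.ndarray,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Seeded 2-D t-SNE embedding of sampled configurations.

    ``points`` are the high-dimensional configuration features (center-of-
    mass coordinates or full search-space points); energies ride along for
    coloring. Deterministic for a fixed seed (PCA initialization).
    """
    cfg = cfg or AnalysisConfig()
    points = np.atleast_2d(np.asarray(points, dtype=float))
    energies = np.asarray(energies, dtype=float).ravel()
    if len(points) != len(energies):
        raise ValueError("points and energies length mismatch")
    if len(points) < 3 * cfg.perplexity:
        raise ValueError(
            f"{len(points)} points is too few for perplexity {cfg.perplexity}; "
            "lower the perplexity"
        )
    ts = TSNE(
        n_components=2,
        perplexity=cfg.perplexity,
        random_state=cfg.seed,
        init="pca",
    )
    emb = ts.fit_transform(points)
    return pd.DataFrame(
        {"tsne1": emb[:, 0], "tsne2": emb[:, 1], "energy": energies}
    )


def analyze_system(
    system: AdsorptionSystem,
    e_complex: float,
    e_cluster: float,
    e_molecule: float,
    cfg: AnalysisConfig | None = None,
    cluster_faces=None,
    keggin=None,
) -> InteractionReport:
    """Full analytics for one structure; site classification is attached
    when the Keggin cluster (and optionally precomputed faces) is given."""
    cfg = cfg or AnalysisConfig()
    count, pairs = mdc(system, cfg)
    dmin, pair = min_distance(system)
    site = None
    if keggin is not None:
        from .keggin import classify_site
        from .structures import center_of_mass

        try:
            site = classify_site(keggin, center_of_mass(system.adsorbate), cluster_faces)
        except ValueError:
            site = None  # COM inside the hull: no face assignment
    return InteractionReport(
        e_complex=e_complex,
        e_cluster=e_cluster,
        e_molecule=e_molecule,
        e_b=binding_energy(e_complex, e_cluster, e_molecule),
        hbonds=detect_hbonds(system, cfg),
        min_distance=dmin,
        min_distance_pair=pair,
        mdc=count,
        mdc_pairs=pairs,
        site=site,
    )


def ensemble_report(reports: list[InteractionReport]) -> pd.DataFrame:
    """One row per structure: E, E_b, contact statistics, site, H-bond count."""
    rows = []
    for r in reports:
        rows.append(
            {
                "E_complex": r.e_complex,
                "E_b": r.e_b,
                "mdc": r.mdc,
                "min_distance": r.min_distance,
                "site": None if r.site is None else r.site[0],
                "n_hbonds": len(r.hbonds),
                "n_hbonds_inter": sum(1 for h in r.hbonds if not h.intra),
            }
        )
    return pd.DataFrame(rows)
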