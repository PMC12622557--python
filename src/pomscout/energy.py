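"""Calculator contract and the two built-in desk-scale energy backends.

The pipeline talks to a minimal calculator interface (evaluate → eV,
optional gradient) so the search and refinement machinery is agnostic to the
energy source. Two backends ship with the package:

* an empirical interaction potential (Lennard-Jones + screened Coulomb +
  torsion barriers + a short-range hydrogen-bond well) that makes the full
  pipeline executable on a desk;
* analytic planted-well landscapes (from :mod:`pomscout.synthetic`) whose
  minima are known exactly, enabling oracle tests of the search machinery.

The empirical potential is deliberately NOT fitted to any quantum-chemical
reference: it reproduces pipeline behaviour (bound poses, contact-driven
stabilization), not literature energetics. An adapter stub at the bottom of
this module documents how an external first-principles code would satisfy
the same contract.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
from scipy.optimize import minimize

from .periodic_data import covalent_radius
from .structures import AdsorptionSystem, Molecule, detect_rotatable_torsions, measure_torsion
from .synthetic import PlantedLandscape

__all__ = [
    "Calculator",
    "EmpiricalPotentialParams",
    "empirical_energy",
    "EmpiricalCalculator",
    "PlantedCalculator",
    "FunctionCalculator",
    "assign_default_charges",
    "detect_unphysical",
    "relax",
    "finite_difference_gradient",
    "COULOMB_CONSTANT",
]

# e^2 / (4 pi eps0), eV * Angstrom
COULOMB_CONSTANT = 14.3996


class Calculator(Protocol):
    """Energy backend contract: deterministic for fixed input and params."""

    name: str

    def evaluate(self, x) -> float: ...

    def gradient(self, x) -> np.ndarray: ...

    @property
    def params_hash(self) -> str: ...


def finite_difference_gradient(
    f: Callable[[np.ndarray], float], x: np.ndarray, h: float = 1e-4
) -> np.ndarray:
    """Central finite differences — the fallback when a backend lacks
    analytic gradients."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for k in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp.flat[k] += h
        xm.flat[k] -= h
        g.flat[k] = (f(xp) - f(xm)) / (2.0 * h)
    return g


# ---------------------------------------------------------------------------
# Empirical interaction potential
# ---------------------------------------------------------------------------

# per-element LJ well depths (eV) and diameters (Å); pairs combine by
# Lorentz-Berthelot rules
_LJ_EPSILON = {
    "H": 0.0020,
    "C": 0.0040,
    "N": 0.0070,
    "O": 0.0090,
    "S": 0.0120,
    "P": 0.0120,
    "Mo": 0.0050,
}
_LJ_SIGMA = {
    "H": 2.50,
    "C": 3.40,
    "N": 3.25,
    "O": 3.10,
    "S": 3.60,
    "P": 3.70,
    "Mo": 2.90,
}


@dataclass(frozen=True)
class EmpiricalPotentialParams:
    """Parameters of the built-in stand-in potential.

    ``hbond_sigma`` is the equilibrium donor-H···acceptor distance of the
    10-12 hydrogen-bond well; ``dielectric`` scales the Coulomb term down to
    mimic screening. Defaults are documented constants, not fits.
    """

    lj_epsilon: dict = field(default_factory=lambda: dict(_LJ_EPSILON))
    lj_sigma: dict = field(default_factory=lambda: dict(_LJ_SIGMA))
    dielectric: float = 4.0
    torsion_barrier: float = 0.02  # eV, 3-fold term per rotatable torsion
    hbond_depth: float = 0.25  # eV
    hbond_sigma: float = 1.90  # Å
    hbond_cutoff: float = 4.0  # Å, beyond this the 10-12 term is negligible
    scale14: float = 0.5

    def pair_lj(self, ei: str, ej: str) -> tuple[float, float]:
        try:
            eps = np.sqrt(self.lj_epsilon[ei] * self.lj_epsilon[ej])
            sig = 0.5 * (self.lj_sigma[ei] + self.lj_sigma[ej])
        except KeyError as exc:
            raise KeyError(f"no LJ parameters for element pair ({ei}, {ej})") from exc
        return eps, sig

    @property
    def params_hash(self) -> str:
        blob = json.dumps(
            {
                "eps": self.lj_epsilon,
                "sig": self.lj_sigma,
                "diel": self.dielectric,
                "tors": self.torsion_barrier,
                "hbd": self.hbond_depth,
                "hbs": self.hbond_sigma,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_POLAR = frozenset({"N", "O", "S"})

# context-dependent partial charges (e) for the stand-in Coulomb term;
# residual charge is spread uniformly so fragments hit their formal charge
_CHARGE_RULES = {
    ("O", "terminal-oxygen"): -0.50,
    ("O", "bridging-oxygen"): -0.35,
    ("O", "central-oxygen"): -0.60,
    ("Mo", None): 0.85,
    ("P", None): 1.20,
}
_MOLECULE_CHARGES = {"N": -0.70, "O": -0.50, "S": -0.25, "C": 0.05}


def assign_default_charges(mol: Molecule) -> Molecule:
    """Attach the shipped heuristic partial charges (stand-in, not Mülliken).

    Polar hydrogens (bound to N/O/S) get +0.35 e, other H +0.05 e; heavy
    atoms follow the element/tag table; any residual is distributed evenly
    so the total matches the fragment's formal charge exactly.
    """
    q = np.zeros(mol.n_atoms)
    adj = mol.adjacency()
    for i, el in enumerate(mol.elements):
        tag = mol.tags[i] if mol.tags else None
        if (el, tag) in _CHARGE_RULES:
            q[i] = _CHARGE_RULES[(el, tag)]
        elif (el, None) in _CHARGE_RULES:
            q[i] = _CHARGE_RULES[(el, None)]
        elif el == "H":
            parent_polar = any(mol.elements[j] in _POLAR for j in adj[i])
            q[i] = 0.35 if parent_polar else 0.05
        else:
            q[i] = _MOLECULE_CHARGES.get(el, 0.0)
    q += (mol.formal_charge - q.sum()) / mol.n_atoms
    out = mol.copy()
    out.partial_charges = q
    return out


def _bond_separation(mol: Molecule, max_sep: int = 3) -> np.ndarray:
    """Topological distances up to ``max_sep`` bonds (else a large sentinel)."""
    n = mol.n_atoms
    sep = np.full((n, n), 99, dtype=int)
    np.fill_diagonal(sep, 0)
    adj = mol.adjacency()
    for start in range(n):
        frontier = [start]
        for depth in range(1, max_sep + 1):
            nxt = []
            for v in frontier:
                for w in adj[v]:
                    if sep[start, w] > depth:
                        sep[start, w] = depth
                        nxt.append(w)
            frontier = nxt
    return sep


def _is_donor_h(mol: Molecule, adj: list[list[int]], i: int) -> bool:
    return mol.elements[i] == "H" and any(mol.elements[j] in _POLAR for j in adj[i])


def _charges(mol: Molecule) -> np.ndarray:
    if mol.partial_charges is not None:
        return mol.partial_charges
    return assign_default_charges(mol).partial_charges


class _PairContext:
    """Precomputed distance-independent pair matrices between two atom sets.

    All terms depend on geometry only through the distance matrix, so the
    LJ coefficients, Coulomb prefactors and hydrogen-bond pair mask can be
    cached per topology and reused across poses/conformers.
    """

    def __init__(
        self,
        a: Molecule,
        b: Molecule,
        params: EmpiricalPotentialParams,
        scale: np.ndarray | None = None,
    ) -> None:
        qa, qb = _charges(a), _charges(b)
        adj_a, adj_b = a.adjacency(), b.adjacency()
        donors_a = np.array([_is_donor_h(a, adj_a, i) for i in range(a.n_atoms)])
        donors_b = np.array([_is_donor_h(b, adj_b, j) for j in range(b.n_atoms)])
        polar_a = np.array([e in _POLAR for e in a.elements])
        polar_b = np.array([e in _POLAR for e in b.elements])
        self.hb = donors_a[:, None] & polar_b[None, :]
        self.hb |= donors_b[None, :] & polar_a[:, None]
        eps = np.empty((a.n_atoms, b.n_atoms))
        sig = np.empty_like(eps)
        for i, ei in enumerate(a.elements):
            for j, ej in enumerate(b.elements):
                eps[i, j], sig[i, j] = params.pair_lj(ei, ej)
        lj = ~self.hb
        self.lj_a = np.where(lj, 4.0 * eps * sig**12, 0.0)
        self.lj_b = np.where(lj, 4.0 * eps * sig**6, 0.0)
        self.coul = COULOMB_CONSTANT * np.outer(qa, qb) / params.dielectric
        self.hb_a = np.where(self.hb, 5.0 * params.hbond_depth * params.hbond_sigma**12, 0.0)
        self.hb_b = np.where(self.hb, 6.0 * params.hbond_depth * params.hbond_sigma**10, 0.0)
        self.hb_cutoff = params.hbond_cutoff
        self.scale = np.ones_like(eps) if scale is None else scale

    def energy(self, d: np.ndarray) -> float:
        inv = 1.0 / d
        inv2 = inv * inv
        inv6 = inv2 * inv2 * inv2
        inv10 = inv6 * inv2 * inv2
        inv12 = inv6 * inv6
        e = self.coul * inv + self.lj_a * inv12 - self.lj_b * inv6
        hb_on = (d < self.hb_cutoff) & self.hb
        e += np.where(hb_on, self.hb_a * inv12 - self.hb_b * inv10, 0.0)
        return float((self.scale * e).sum())


class _IntraContext:
    """Cached intramolecular terms: torsion list + nonbonded pair context.

    Nonbonded pairs closer than 3 bonds are excluded (rigid internal
    geometry); 1-4 pairs are scaled by ``scale14``.
    """

    def __init__(self, mol: Molecule, params: EmpiricalPotentialParams) -> None:
        self.torsions = detect_rotatable_torsions(mol)
        self.barrier = params.torsion_barrier
        n = mol.n_atoms
        sep = _bond_separation(mol)
        scale = np.zeros((n, n))
        scale[sep == 3] = params.scale14
        scale[sep > 3] = 1.0
        scale = np.triu(scale, k=1)  # each unordered pair once
        self.pairs = _PairContext(mol, mol, params, scale=scale)

    def energy(self, mol: Molecule) -> float:
        e = 0.0
        for torsion in self.torsions:
            theta = np.radians(measure_torsion(mol, torsion))
            e += 0.5 * self.barrier * (1.0 + np.cos(3.0 * theta))
        if mol.n_atoms >= 2:
            d = np.linalg.norm(mol.coords[:, None] - mol.coords[None, :], axis=-1)
            np.fill_diagonal(d, 1.0)  # masked by the zero diagonal scale
            e += self.pairs.energy(d)
        return e


def empirical_energy(
    system: Molecule | AdsorptionSystem,
    params: EmpiricalPotentialParams | None = None,
    _ctx: dict | None = None,
) -> float:
    """Total energy (eV) of a molecule or cluster+adsorbate composite.

    Inter-fragment LJ + screened Coulomb + hydrogen-bond wells, plus
    intra-fragment torsion and long-range nonbonded terms (pairs ≥3 bonds
    apart; 1-4 scaled). Additive over non-interacting fragments by
    construction. Raises if any atom pair is closer than 0.05 Å.
    """
    params = params or EmpiricalPotentialParams()
    ctx = _ctx if _ctx is not None else {}
    if isinstance(system, AdsorptionSystem):
        d = system.inter_distances()
        if d.min() < 0.05:
            raise ValueError("overlapping atoms closer than 0.05 Å")
        if "inter" not in ctx:
            ctx["inter"] = _PairContext(system.cluster, system.adsorbate, params)
            ctx["intra_cluster"] = _IntraContext(system.cluster, params)
            ctx["intra_adsorbate"] = _IntraContext(system.adsorbate, params)
        return (
            ctx["inter"].energy(d)
            + ctx["intra_cluster"].energy(system.cluster)
            + ctx["intra_adsorbate"].energy(system.adsorbate)
        )
    if "intra" not in ctx:
        ctx["intra"] = _IntraContext(system, params)
    return ctx["intra"].energy(system)


# ---------------------------------------------------------------------------
# Calculators
# ---------------------------------------------------------------------------


@dataclass
class PlantedCalculator:
    """Analytic planted-landscape backend: evaluates search-space points."""

    landscape: PlantedLandscape
    name: str = "planted"

    def evaluate(self, q: np.ndarray) -> float:
        return self.landscape.energy(np.asarray(q, dtype=float))

    def gradient(self, q: np.ndarray) -> np.ndarray:
        return self.landscape.gradient(np.asarray(q, dtype=float))

    @property
    def params_hash(self) -> str:
        blob = self.landscape.centers.tobytes() + self.landscape.depths.tobytes()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class FunctionCalculator:
    """Wrap an arbitrary scalar function of a coordinate vector."""

    func: Callable[[np.ndarray], float]
    name: str = "function"
    grad: Callable[[np.ndarray], np.ndarray] | None = None

    def evaluate(self, x) -> float:
        return float(self.func(np.asarray(x, dtype=float)))

    def gradient(self, x) -> np.ndarray:
        if self.grad is not None:
            return self.grad(np.asarray(x, dtype=float))
        return finite_difference_gradient(self.func, np.asarray(x, dtype=float))

    @property
    def params_hash(self) -> str:
        return "function"


@dataclass
class EmpiricalCalculator:
    """Empirical potential over a search space: evaluates points by
    realizing the geometry and summing the potential."""

    space: "object"  # SearchSpace; kept loose to avoid a circular import
    params: EmpiricalPotentialParams = field(default_factory=EmpiricalPotentialParams)
    name: str = "empirical"
    _ctx: dict = field(default_factory=dict, repr=False)

    def realize(self, q: np.ndarray):
        return self.space.realize(np.asarray(q, dtype=float))

    def evaluate(self, q: np.ndarray) -> float:
        # the space realizes a fixed topology, so pair contexts are reusable
        return empirical_energy(self.realize(q), self.params, _ctx=self._ctx)

    def gradient(self, q: np.ndarray) -> np.ndarray:
        return finite_difference_gradient(self.evaluate, np.asarray(q, dtype=float))

    @property
    def params_hash(self) -> str:
        return self.params.params_hash


# ---------------------------------------------------------------------------
# Clash detection and relaxation
# ---------------------------------------------------------------------------


def detect_unphysical(
    system: Molecule | AdsorptionSystem, scale: float = 0.6
) -> tuple[bool, list[tuple[int, int]]]:
    """Flag geometries with non-bonded contacts below ``scale`` × summed
    covalent radii. Returns (flag, offending pairs in combined indexing)."""
    mol = system.combined() if isinstance(system, AdsorptionSystem) else system
    radii = np.array([covalent_radius(e) for e in mol.elements])
    d = np.linalg.norm(mol.coords[:, None] - mol.coords[None, :], axis=-1)
    cutoff = scale * (radii[:, None] + radii[None, :])
    bonded = {tuple(sorted(b)) for b in mol.bonds}
    bad = [
        (i, j)
        for i in range(mol.n_atoms)
        for j in range(i + 1, mol.n_atoms)
        if (i, j) not in bonded and d[i, j] < cutoff[i, j]
    ]
    return bool(bad), bad


@dataclass
class RelaxResult:
    x: np.ndarray
    energy: float
    converged: bool
    steps: int


def relax(
    x0: np.ndarray,
    calc: Calculator,
    max_steps: int = 100,
    f_tol: float = 0.05,
    bounds: list[tuple[float, float]] | None = None,
) -> RelaxResult:
    """Gradient-based local minimization of a coordinate vector.

    Runs L-BFGS-B for at most ``max_steps`` iterations or until the largest
    gradient component falls below ``f_tol`` (eV/Å for Cartesian systems,
    eV per coordinate unit otherwise). Accepted steps never increase the
    energy (line-search descent). Raises on non-finite energies or forces,
    reporting the offending coordinates.
    """
    x0 = np.asarray(x0, dtype=float).ravel()

    def fun(x: np.ndarray) -> tuple[float, np.ndarray]:
        try:
            e = calc.evaluate(x)
            g = np.asarray(calc.gradient(x), dtype=float).ravel()
        except ValueError:
            # inaccessible geometry (e.g. overlapping atoms) probed by the
            # line search: huge finite penalty makes it backtrack
            return 1e8, np.zeros_like(x)
        if not np.isfinite(e) or not np.all(np.isfinite(g)):
            raise FloatingPointError(
                f"non-finite energy/force at coordinates {x.tolist()}"
            )
        return float(e), g

    e0, g0 = fun(x0)
    if np.abs(g0).max() < f_tol:
        return RelaxResult(x=x0, energy=e0, converged=True, steps=0)

    res = minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_steps, "gtol": f_tol, "ftol": 0.0},
    )
    x = np.asarray(res.x)
    e, g = fun(x)
    converged = bool(np.abs(g).max() < f_tol)
    return RelaxResult(x=x, energy=e, converged=converged, steps=int(res.nit))


def relax_geometry(
    mol: Molecule,
    energy_fn: Callable[[Molecule], float],
    max_steps: int = 100,
    f_tol: float = 0.05,
) -> tuple[Molecule, RelaxResult]:
    """Cartesian relaxation of a molecule under an energy function of the
    geometry (gradient by central finite differences)."""

    def f(x: np.ndarray) -> float:
        return energy_fn(mol.with_coords(x.reshape(-1, 3)))

    calc = FunctionCalculator(func=f, name="cartesian")
    result = relax(mol.coords.ravel(), calc, max_steps=max_steps, f_tol=f_tol)
    return mol.with_coords(result.x.reshape(-1, 3)), result


class ExternalCodeAdapter:
    """Documentation stub: how a first-principles code would plug in.

    A production adapter would (1) write the realized geometry to the code's
    input format, (2) dispatch a single-point or relaxation job, (3) parse
    total energy (eV) and forces (eV/Å) from the output, and (4) surface
    them through :meth:`evaluate` / :meth:`gradient`. Functional, basis and
    convergence settings would feed ``params_hash`` so mixed-provenance
    energies are rejected downstream. Not implemented here: the package's
    scope ends at the calculator contract.
    """

    def __init__(self, *_, **__):
        raise NotImplementedError(
            "adapter stub; supply a Calculator implementation instead"
        )
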