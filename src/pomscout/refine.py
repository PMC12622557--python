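"""Surrogate minima mining and the multi-stage refinement funnel.

The funnel mirrors the staged filtering used in active-learning structure
searches: mined surrogate minima receive true single-point energies,
sterically impossible geometries are removed, survivors are relaxed for a
capped number of steps, an energy window keeps the low-lying set, K-means
on the relaxed energies picks representative structures, those are relaxed
to convergence, and duplicates are merged. Every rejection is logged with
its stage and reason; attrition is monotone by construction (the
representative-relaxation stage preserves count).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation
from sklearn.cluster import KMeans

from .bo import SearchSpace
from .energy import Calculator, detect_unphysical, relax
from .gp import SurrogateModel
from .structures import AdsorptionSystem, Molecule

__all__ = [
    "Stage",
    "CandidateStructure",
    "FunnelConfig",
    "FunnelReport",
    "mine_minima",
    "select_low_energy",
    "run_funnel",
    "proximity_filter",
    "superpose_rmsd",
]


class Stage(str, Enum):
    MINED = "mined"
    SINGLEPOINT = "singlepoint"
    PHYSICAL = "physical"
    RELAXED100 = "relaxed100"
    WINDOW = "window"
    KMEANS_CENTER = "kmeans_center"
    FINAL_UNIQUE = "final_unique"
    REJECTED = "rejected"


_ORDER = [
    Stage.MINED,
    Stage.SINGLEPOINT,
    Stage.PHYSICAL,
    Stage.RELAXED100,
    Stage.WINDOW,
    Stage.KMEANS_CENTER,
    Stage.FINAL_UNIQUE,
]


@dataclass
class CandidateStructure:
    """One candidate moving through the funnel.

    Energies carry their provenance: surrogate (GP mean at the mined point),
    single-point (true calculator at the mined point), relaxed (after local
    minimization). ``stage`` only ever moves forward.
    """

    point: np.ndarray
    energy_surrogate: float
    geometry: object | None = None  # Molecule or AdsorptionSystem
    energy_singlepoint: float | None = None
    energy_relaxed: float | None = None
    stage: Stage = Stage.MINED
    reject_reason: str | None = None

    def advance(self, stage: Stage) -> None:
        if self.stage == Stage.REJECTED:
            raise ValueError("cannot advance a rejected candidate")
        if _ORDER.index(stage) < _ORDER.index(self.stage):
            raise ValueError(f"stage may not move backward ({self.stage} -> {stage})")
        self.stage = stage

    def reject(self, stage: Stage, reason: str) -> None:
        self.stage = Stage.REJECTED
        self.reject_reason = f"{stage.value}: {reason}"


@dataclass(frozen=True)
class FunnelConfig:
    """Stage parameters; defaults follow common refinement practice."""

    relax_cap: int = 100  # capped pre-screen relaxation steps
    window: float = 0.2  # eV above the relaxed minimum
    k: int = 15  # K-means representative count
    dedup_energy_tol: float = 0.01  # eV
    dedup_rmsd_tol: float = 0.3  # Å
    dedup_point_tol: float = 0.05  # normalized units, for point-only dedup
    clash_scale: float = 0.6
    final_relax_cap: int = 2000
    f_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window <= 0 or self.k < 1:
            raise ValueError("window must be positive and k >= 1")
        if min(self.dedup_energy_tol, self.dedup_rmsd_tol) <= 0:
            raise ValueError("dedup tolerances must be positive")


@dataclass
class FunnelReport:
    """Survivors + per-stage attrition table + per-candidate log."""

    final: list[CandidateStructure]
    attrition: pd.DataFrame
    candidates: list[CandidateStructure] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.candidates):
            rows.append(
                {
                    "candidate": i,
                    "stage": c.stage.value,
                    "E_surrogate": c.energy_surrogate,
                    "E_singlepoint": c.energy_singlepoint,
                    "E_relaxed": c.energy_relaxed,
                    "reject_reason": c.reject_reason,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Surrogate minima mining
# ---------------------------------------------------------------------------


def mine_minima(
    model: SurrogateModel,
    space: SearchSpace,
    n_starts: int = 64,
    seed: int = 0,
) -> list[CandidateStructure]:
    """Multi-start minimization of the GP posterior mean.

    Starts from a seeded quasi-random design plus every training point, so
    each basin the surrogate has actually observed contributes a start.
    Converged endpoints are deduplicated by periodic-aware distance
    (< 0.05 of the normalized range) and surrogate-energy difference
    (< 1e-3 eV), then sorted by surrogate energy.
    """

    def mean(u: np.ndarray) -> float:
        return float(model.predict(u[None, :], return_std=False)[0])

    starts = [space.normalize(q) for q in space.sobol(n_starts, seed)]
    starts.extend(model.X)
    found: list[tuple[np.ndarray, float]] = []
    for u0 in starts:
        res = minimize(
            mean,
            np.clip(u0, 0.0, 1.0),
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * space.dimension,
            options={"maxiter": 200},
        )
        u = res.x
        e = float(res.fun)
        dup = False
        for uk, ek in found:
            du = u - uk
            per = space.periodic
            du[per] = (du[per] + 0.5) % 1.0 - 0.5
            if np.linalg.norm(du) < 0.05 and abs(e - ek) < 1e-3:
                dup = True
                break
        if not dup:
            found.append((u, e))
    found.sort(key=lambda t: t[1])
    out = []
    for u, e in found:
        q = space.wrap(space.denormalize(u))
        geom = space.realize(q) if space.realize is not None else None
        out.append(CandidateStructure(point=q, energy_surrogate=e, geometry=geom))
    return out


def select_low_energy(
    trace,
    space: SearchSpace,
    percentile: float = 50.0,
    dedup_distance: float = 0.05,
) -> list[CandidateStructure]:
    """Low-energy sampled configurations as refinement candidates.

    Selects the successfully evaluated points below the given energy
    percentile — the sampled-ensemble route into the funnel, complementary
    to surrogate minima mining. Near-duplicate points (periodic-aware
    normalized distance < ``dedup_distance``) are merged keeping the lower
    energy.
    """
    ok = trace.records[trace.records["status"] == "ok"]
    if ok.empty:
        return []
    cutoff = float(np.percentile(ok["energy"], percentile))
    rows = ok[ok["energy"] <= cutoff].sort_values("energy")
    out: list[CandidateStructure] = []
    for _, row in rows.iterrows():
        q = row.filter(like="q_").to_numpy(dtype=float)
        if any(
            float(space.periodic_distance(q, c.point)[0]) < dedup_distance
            for c in out
        ):
            continue
        geom = space.realize(q) if space.realize is not None else None
        out.append(
            CandidateStructure(
                point=q,
                energy_surrogate=float(row["energy"]),
                geometry=geom,
                energy_singlepoint=float(row["energy"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Structure comparison
# ---------------------------------------------------------------------------


def superpose_rmsd(a: Molecule, b: Molecule) -> float:
    """Minimal RMSD over proper rotations + translations (Kabsch).

    Requires identical element sequences (atom order is the correspondence).
    Symmetric, and zero iff the structures are congruent.
    """
    if a.n_atoms != b.n_atoms:
        raise ValueError(f"atom-count mismatch: {a.n_atoms} vs {b.n_atoms}")
    if a.elements != b.elements:
        raise ValueError("element sequences differ")
    pa = a.coords - a.coords.mean(axis=0)
    pb = b.coords - b.coords.mean(axis=0)
    _, rssd = Rotation.align_vectors(pa, pb)
    return float(rssd / np.sqrt(a.n_atoms))


def _geometry_molecule(geom) -> Molecule | None:
    if isinstance(geom, AdsorptionSystem):
        return geom.combined()
    if isinstance(geom, Molecule):
        return geom
    return None


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def proximity_filter(
    candidates: list[CandidateStructure], max_min_distance: float = 4.0
) -> list[CandidateStructure]:
    """Keep candidates whose fragments actually interact: the minimal
    inter-fragment distance must not exceed ``max_min_distance`` (Å)."""
    kept = []
    for c in candidates:
        if not isinstance(c.geometry, AdsorptionSystem):
            kept.append(c)
            continue
        dmin = float(c.geometry.inter_distances().min())
        if dmin <= max_min_distance:
            kept.append(c)
        else:
            c.reject(
                c.stage if c.stage != Stage.REJECTED else Stage.MINED,
                f"beyond interaction distance ({dmin:.2f} Å > {max_min_distance} Å)",
            )
    return kept


# ---------------------------------------------------------------------------
# The funnel
# ---------------------------------------------------------------------------


def run_funnel(
    candidates: list[CandidateStructure],
    calc: Calculator,
    cfg: FunnelConfig,
    space: SearchSpace | None = None,
) -> FunnelReport:
    """Push mined candidates through the staged refinement funnel.

    Stages, in order: (A) true single-point energies at the mined points;
    (B) removal of sterically unphysical geometries; (C) relaxation capped
    at ``relax_cap`` steps; (D) energy window ``window`` above the relaxed
    minimum; (E) K-means (seeded k-means++) on the 1-D relaxed energies,
    keeping the candidate nearest each center; (F) relaxation of the
    representatives to convergence; (G) duplicate merging, keeping the
    lower-energy member of each pair. Raises if nothing survives, with the
    per-stage attrition attached to the error message.
    """
    if not candidates:
        raise ValueError("no candidates supplied")
    attrition_rows = []

    def log_stage(stage: Stage, n_in: int, n_out: int) -> None:
        attrition_rows.append(
            {"stage": stage.value, "entered": n_in, "survived": n_out}
        )

    live = list(candidates)

    # A: single-point energies
    n_in = len(live)
    survivors = []
    for c in live:
        try:
            c.energy_singlepoint = float(calc.evaluate(c.point))
            c.advance(Stage.SINGLEPOINT)
            survivors.append(c)
        except Exception as exc:
            c.reject(Stage.SINGLEPOINT, f"single-point failed: {exc}")
    log_stage(Stage.SINGLEPOINT, n_in, len(survivors))
    live = survivors

    # B: unphysical removal
    n_in = len(live)
    survivors = []
    for c in live:
        mol = _geometry_molecule(c.geometry)
        if mol is not None:
            flagged, pairs = detect_unphysical(
                c.geometry if isinstance(c.geometry, AdsorptionSystem) else mol,
                scale=cfg.clash_scale,
            )
            if flagged:
                c.reject(Stage.PHYSICAL, f"clashing pairs {pairs[:3]}")
                continue
        c.advance(Stage.PHYSICAL)
        survivors.append(c)
    log_stage(Stage.PHYSICAL, n_in, len(survivors))
    live = survivors

    # C: capped relaxation in search-space coordinates
    n_in = len(live)
    bounds = None
    if space is not None:
        bounds = [
            (None, None) if d.periodic else (d.lower, d.upper) for d in space.dims
        ]
    for c in live:
        res = relax(c.point, calc, max_steps=cfg.relax_cap, f_tol=cfg.f_tol, bounds=bounds)
        c.point = space.wrap(res.x) if space is not None else res.x
        c.energy_relaxed = res.energy
        if space is not None and space.realize is not None:
            c.geometry = space.realize(c.point)
        c.advance(Stage.RELAXED100)
    log_stage(Stage.RELAXED100, n_in, len(live))

    if not live:
        raise RuntimeError(
            "all candidates rejected\n" + pd.DataFrame(attrition_rows).to_string()
        )

    # D: energy window vs the post-relaxation minimum
    n_in = len(live)
    e_min = min(c.energy_relaxed for c in live)
    survivors = []
    for c in live:
        if c.energy_relaxed - e_min <= cfg.window:
            c.advance(Stage.WINDOW)
            survivors.append(c)
        else:
            c.reject(
                Stage.WINDOW,
                f"ΔE = {c.energy_relaxed - e_min:.3f} eV above window {cfg.window} eV",
            )
    log_stage(Stage.WINDOW, n_in, len(survivors))
    live = survivors

    # E: K-means on the 1-D relaxed energies; keep the nearest candidate.
    # k >= |candidates| degenerates to the identity map.
    n_in = len(live)
    k = min(cfg.k, len(live))
    if k == len(live):
        keep_idx = set(range(len(live)))
    else:
        energies = np.array([c.energy_relaxed for c in live]).reshape(-1, 1)
        km = KMeans(n_clusters=k, n_init=10, random_state=cfg.seed).fit(energies)
        keep_idx = set()
        for center in km.cluster_centers_:
            keep_idx.add(int(np.argmin(np.abs(energies[:, 0] - center[0]))))
    survivors = []
    for i, c in enumerate(live):
        if i in keep_idx:
            c.advance(Stage.KMEANS_CENTER)
            survivors.append(c)
        else:
            c.reject(Stage.KMEANS_CENTER, "not a representative energy-cluster center")
    log_stage(Stage.KMEANS_CENTER, n_in, len(survivors))
    live = survivors

    # F: relax representatives to convergence (count preserved)
    n_in = len(live)
    for c in live:
        res = relax(
            c.point, calc, max_steps=cfg.final_relax_cap, f_tol=cfg.f_tol, bounds=bounds
        )
        c.point = space.wrap(res.x) if space is not None else res.x
        c.energy_relaxed = res.energy
        if space is not None and space.realize is not None:
            c.geometry = space.realize(c.point)
    log_stage(Stage.FINAL_UNIQUE, n_in, len(live))

    # G: duplicate elimination (energy + geometry or point distance)
    live.sort(key=lambda c: c.energy_relaxed)
    unique: list[CandidateStructure] = []
    for c in live:
        dup_of = None
        for u in unique:
            if abs(c.energy_relaxed - u.energy_relaxed) >= cfg.dedup_energy_tol:
                continue
            mol_c = _geometry_molecule(c.geometry)
            mol_u = _geometry_molecule(u.geometry)
            if mol_c is not None and mol_u is not None:
                if superpose_rmsd(mol_c, mol_u) < cfg.dedup_rmsd_tol:
                    dup_of = u
                    break
            elif space is not None:
                dist = float(space.periodic_distance(c.point, u.point)[0])
                if dist < cfg.dedup_point_tol:
                    dup_of = u
                    break
        if dup_of is None:
            c.advance(Stage.FINAL_UNIQUE)
            unique.append(c)
        else:
            c.reject(Stage.FINAL_UNIQUE, "duplicate of a lower-energy structure")
    attrition_rows.append(
        {"stage": "dedup", "entered": len(live), "survived": len(unique)}
    )

    if not unique:
        raise RuntimeError(
            "all candidates rejected\n" + pd.DataFrame(attrition_rows).to_string()
        )
    return FunnelReport(
        final=unique,
        attrition=pd.DataFrame(attrition_rows),
        candidates=list(candidates),
    )
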