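"""Surrogate minima mining, the refinement funnel, superposition RMSD."""

import numpy as np
import pytest

from pomscout.bo import Dimension, SearchSpace
from pomscout.energy import PlantedCalculator
from pomscout.gp import fit_surrogate
from pomscout.refine import (
    CandidateStructure,
    FunnelConfig,
    Stage,
    mine_minima,
    proximity_filter,
    run_funnel,
    superpose_rmsd,
)
from pomscout.structures import AdsorptionSystem, Molecule, RigidPose, apply_pose
from pomscout.synthetic import PlantedLandscape, make_landscape


def _fit_dense(lands, space, n=256, seed=5):
    X = space.sobol(n, seed=seed)
    y = np.array([lands.energy(q) for q in X])
    return fit_surrogate(
        np.array([space.normalize(q) for q in X]), y, periodic=space.periodic
    )


class TestMineMinima:
    def test_single_bowl_yields_one_minimum(self, box_space_2d):
        # convex quadratic bowl: the surrogate has exactly one basin
        X = box_space_2d.sobol(128, seed=9)
        y = np.array([np.sum((q - 5.0) ** 2) for q in X])
        model = fit_surrogate(
            np.array([box_space_2d.normalize(q) for q in X]),
            y,
            periodic=box_space_2d.periodic,
        )
        mined = mine_minima(model, box_space_2d, n_starts=32, seed=1)
        assert len(mined) == 1
        np.testing.assert_allclose(mined[0].point, [5.0, 5.0], atol=0.2)

    def test_three_wells_recovered_at_centers(self, box_space_2d):
        lands = make_landscape(dimension=2, n_wells=3, seed=11)
        model = _fit_dense(lands, box_space_2d)
        mined = mine_minima(model, box_space_2d, n_starts=64, seed=1)
        # every planted center matched by some mined minimum within width/10
        for k, c in enumerate(lands.centers):
            dmin = min(np.linalg.norm(m.point - c) for m in mined)
            assert dmin < lands.widths[k] / 10

    def test_count_bounded_by_starts_plus_training(self, box_space_2d):
        lands = make_landscape(dimension=2, n_wells=2, seed=3)
        model = _fit_dense(lands, box_space_2d, n=64)
        mined = mine_minima(model, box_space_2d, n_starts=16, seed=0)
        assert len(mined) <= 16 + model.n_train

    def test_sorted_by_surrogate_energy(self, box_space_2d):
        lands = make_landscape(dimension=2, n_wells=3, seed=11)
        model = _fit_dense(lands, box_space_2d)
        mined = mine_minima(model, box_space_2d, n_starts=64, seed=1)
        energies = [m.energy_surrogate for m in mined]
        assert energies == sorted(energies)


class TestFunnel:
    def _landscape_two_survivors(self):
        """Explicit wells at depths 1.0/0.9/0.5: exactly two inside the
        0.2 eV window."""
        centers = np.array([[2.0, 2.0], [8.0, 8.0], [2.0, 8.0]])
        return PlantedLandscape(
            dimension=2,
            centers=centers,
            depths=np.array([1.0, 0.9, 0.5]),
            widths=np.array([0.8, 0.8, 0.8]),
            lower=np.zeros(2),
            upper=np.full(2, 10.0),
            periodic=np.zeros(2, bool),
        )

    def test_stage_d_energy_window_exact(self, box_space_2d):
        """Toy energies [0, 0.1, 0.25] with window 0.2 -> 2 survivors."""
        offsets = [0.0, 0.1, 0.25]
        lands = self._landscape_two_survivors()

        class Shifted:
            name = "shifted"
            params_hash = "s"

            def evaluate(self, q):
                # three flat candidates at controlled relative energies
                k = int(round(q[0]))
                return offsets[k]

            def gradient(self, q):
                return np.zeros_like(q)

        cands = [
            CandidateStructure(point=np.array([float(k), 0.0]), energy_surrogate=0.0)
            for k in range(3)
        ]
        report = run_funnel(
            cands, Shifted(), FunnelConfig(window=0.2, k=10, seed=0)
        )
        assert len(report.final) == 2
        row = report.attrition.set_index("stage")
        assert row.loc["window", "entered"] == 3
        assert row.loc["window", "survived"] == 2

    def test_end_to_end_final_equals_wells_in_window(self, box_space_2d):
        lands = self._landscape_two_survivors()
        calc = PlantedCalculator(lands)
        model = _fit_dense(lands, box_space_2d)
        mined = mine_minima(model, box_space_2d, n_starts=64, seed=2)
        report = run_funnel(
            mined, calc, FunnelConfig(window=0.2, k=15, seed=0), space=box_space_2d
        )
        finals = sorted(report.final, key=lambda c: c.energy_relaxed)
        assert len(finals) == 2
        for c, well in zip(finals, (0, 1)):
            assert (
                np.linalg.norm(c.point - lands.centers[well])
                < lands.widths[well] / 10
            )

    def test_attrition_monotone(self, box_space_2d):
        lands = self._landscape_two_survivors()
        calc = PlantedCalculator(lands)
        model = _fit_dense(lands, box_space_2d)
        mined = mine_minima(model, box_space_2d, n_starts=64, seed=2)
        report = run_funnel(mined, calc, FunnelConfig(seed=0), space=box_space_2d)
        surv = report.attrition["survived"].to_numpy()
        ent = report.attrition["entered"].to_numpy()
        assert np.all(surv <= ent)
        assert np.all(ent[1:] == surv[:-1])

    def test_wide_window_large_k_stages_de_identity(self, box_space_2d):
        lands = self._landscape_two_survivors()
        calc = PlantedCalculator(lands)
        model = _fit_dense(lands, box_space_2d)
        mined = mine_minima(model, box_space_2d, n_starts=32, seed=2)
        report = run_funnel(
            mined,
            calc,
            FunnelConfig(window=1e6, k=len(mined), seed=0),
            space=box_space_2d,
        )
        row = report.attrition.set_index("stage")
        assert row.loc["window", "entered"] == row.loc["window", "survived"]
        assert row.loc["kmeans_center", "entered"] == row.loc["kmeans_center", "survived"]

    def test_deterministic_given_seed(self, box_space_2d):
        lands = self._landscape_two_survivors()
        calc = PlantedCalculator(lands)
        model = _fit_dense(lands, box_space_2d)

        def run():
            mined = mine_minima(model, box_space_2d, n_starts=48, seed=2)
            rep = run_funnel(mined, calc, FunnelConfig(seed=3), space=box_space_2d)
            return [(tuple(c.point), c.energy_relaxed) for c in rep.final]

        assert run() == run()

    def test_empty_candidates_rejected(self):
        lands = self._landscape_two_survivors()
        with pytest.raises(ValueError):
            run_funnel([], PlantedCalculator(lands), FunnelConfig(seed=0))

    def test_duplicate_geometries_merged(self, gly):
        mol = gly.molecule

        class Flat:
            name = "flat"
            params_hash = "f"

            def evaluate(self, q):
                return -1.0

            def gradient(self, q):
                return np.zeros_like(q)

        cands = [
            CandidateStructure(
                point=np.zeros(2), energy_surrogate=-1.0, geometry=mol.copy()
            )
            for _ in range(3)
        ]
        report = run_funnel(cands, Flat(), FunnelConfig(seed=0))
        assert len(report.final) == 1
        assert sum(1 for c in report.candidates if c.stage == Stage.REJECTED) == 2

    def test_stage_cannot_move_backward(self):
        c = CandidateStructure(point=np.zeros(2), energy_surrogate=0.0)
        c.advance(Stage.WINDOW)
        with pytest.raises(ValueError, match="backward"):
            c.advance(Stage.SINGLEPOINT)


class TestProximityFilter:
    def _system(self, offset):
        a = Molecule(elements=["O"], coords=[[0, 0, 0]])
        b = Molecule(elements=["H"], coords=[[offset, 0, 0]])
        return CandidateStructure(
            point=np.zeros(1),
            energy_surrogate=0.0,
            geometry=AdsorptionSystem(cluster=a, adsorbate=b),
        )

    def test_far_candidate_excluded_contact_kept(self):
        kept = proximity_filter([self._system(100.0), self._system(2.0)], 4.0)
        assert len(kept) == 1
        assert kept[0].geometry.inter_distances().min() == 2.0

    def test_kept_count_monotone_in_threshold(self):
        cands = [self._system(d) for d in (1.0, 3.0, 5.0, 8.0, 12.0)]
        counts = [
            len(proximity_filter([c for c in cands], t)) for t in (2.0, 4.0, 6.0, 10.0)
        ]
        assert counts == sorted(counts)


class TestSuperposeRMSD:
    def test_identical_zero(self, gly):
        assert superpose_rmsd(gly.molecule, gly.molecule) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_zero(self, gly, rng):
        mol = gly.molecule
        moved = apply_pose(
            mol, RigidPose(translation=(3.0, -2.0, 7.0), rotation=(33, -71, 140))
        )
        assert superpose_rmsd(mol, moved) < 1e-9
        assert superpose_rmsd(moved, mol) < 1e-9

    def test_atom_count_mismatch_raises(self, gly):
        other = Molecule(elements=["H"], coords=[[0, 0, 0]])
        with pytest.raises(ValueError, match="mismatch"):
            superpose_rmsd(gly.molecule, other)

    def test_matches_quaternion_grid_oracle(self):
        """Brute-force rotation-grid search on two fixed 4-atom toys."""
        from scipy.spatial.transform import Rotation

        a = Molecule(
            elements=["C", "N", "O", "H"],
            coords=[[0, 0, 0], [1.4, 0, 0], [0, 1.2, 0], [0.3, 0.3, 1.0]],
        )
        b = Molecule(
            elements=["C", "N", "O", "H"],
            coords=[[0, 0, 0], [1.5, 0.1, 0], [0.1, 1.1, 0.2], [0.2, 0.4, 0.9]],
        )
        got = superpose_rmsd(a, b)
        pa = a.coords - a.coords.mean(axis=0)
        pb = b.coords - b.coords.mean(axis=0)

        def rmsd_of_rotvec(v):
            R = Rotation.from_rotvec(v).as_matrix()
            return np.sqrt(np.mean(np.sum((pa - pb @ R.T) ** 2, axis=1)))

        # coarse rotation grid, then derivative-free polish from the best
        rots = Rotation.random(4000, random_state=0)
        vals = [rmsd_of_rotvec(r.as_rotvec()) for r in rots]
        v0 = rots[int(np.argmin(vals))].as_rotvec()
        from scipy.optimize import minimize

        res = minimize(rmsd_of_rotvec, v0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = float(res.fun)
        assert got <= best + 1e-9
        assert abs(got - best) < 1e-4
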