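"""Kabsch superposition, RMSD/Rg/RMSF kernels, and vicinity counting."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from barrelkit import synth, traj
from barrelkit.io import TrajectoryEnsemble, ValidationError


def toy_ensemble(frames, classes=None, resids=None, box=None):
    frames = np.asarray(frames, float)
    n = frames.shape[1]
    atoms = pd.DataFrame({
        "name": ["C"] * n,
        "resid": resids if resids is not None else np.arange(1, n + 1),
        "resname": ["ALA"] * n,
        "mol_class": classes if classes is not None else ["protein"] * n,
    })
    return TrajectoryEnsemble(frames=frames, atoms=atoms, box=box)


class TestKabsch:
    def _cloud(self, rng, n=12):
        return rng.normal(0, 3, size=(n, 3))

    def test_identity_on_equal_sets(self, rng):
        ref = self._cloud(rng)
        R, t, rmsd = traj.kabsch_superpose(ref, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)

    def test_rigid_motion_invariance(self, rng):
        ref = self._cloud(rng)
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ Rz.T + np.array([5.0, -3.0, 2.0])
        _, _, rmsd = traj.kabsch_superpose(ref, mobile)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_random_proper_rotations_leave_rmsd_invariant(self, rng):
        a = self._cloud(rng)
        b = a + rng.normal(0, 0.5, a.shape)
        _, _, base = traj.kabsch_superpose(a, b)
        for seed in range(10):
            R = Rotation.random(random_state=seed).as_matrix()
            shift = rng.normal(0, 10, 3)
            _, _, moved = traj.kabsch_superpose(a @ R.T + shift, b @ R.T + shift)
            assert moved == pytest.approx(base, abs=1e-10)

    def test_matches_rotation_space_search_oracle(self):
        """SVD answer equals a direct numerical minimum over Euler angles on a
        5-atom toy with one displaced atom."""
        ref = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2], [1, 1, 1]],
                       dtype=float)
        mobile = ref.copy()
        mobile[4] += [1.0, 0.0, 0.0]
        _, _, rmsd_svd = traj.kabsch_superpose(ref, mobile)

        ref_c = ref - ref.mean(axis=0)
        mob_c = mobile - mobile.mean(axis=0)

        def cost(angles):
            R = Rotation.from_euler("xyz", angles).as_matrix()
            return np.sqrt(np.mean(np.sum((mob_c @ R.T - ref_c) ** 2, axis=1)))

        best = np.inf
        for a in np.linspace(-np.pi, np.pi, 7):
            for b in np.linspace(-np.pi / 2, np.pi / 2, 5):
                for c in np.linspace(-np.pi, np.pi, 7):
                    res = minimize(cost, x0=[a, b, c], method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-12})
                    best = min(best, res.fun)
        assert rmsd_svd == pytest.approx(best, abs=1e-3)

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValidationError):
            traj.kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_collinear_set_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValidationError, match="collinear"):
            traj.kabsch_superpose(line, line)


class TestRmsdSeries:
    def test_static_trajectory_all_zero(self, rng):
        frame = rng.normal(0, 5, (10, 3))
        ens = toy_ensemble(np.stack([frame] * 4))
        np.testing.assert_allclose(traj.rmsd_series(ens), 0.0, atol=1e-12)

    def test_excluded_mobile_residue_gives_zero(self, rng):
        frame = rng.normal(0, 5, (12, 3))
        moved = frame.copy()
        moved[4] += [3.0, 0, 0]          # resid 5 moves
        ens = toy_ensemble(np.stack([frame, moved]))
        spec = traj.SelectionSpec(molecule_class="protein", exclude_residues=(5, 5))
        series = traj.rmsd_series(ens, 0, spec)
        assert series[1] == pytest.approx(0.0, abs=1e-10)

    def test_single_displaced_atom_closed_form(self, rng):
        # superposition-free displacement: d / sqrt(N) when fit cannot absorb it
        frame = rng.normal(0, 5, (50, 3))
        moved = frame.copy()
        d = 0.8
        moved[0] += [d, 0, 0]
        ens = toy_ensemble(np.stack([frame, moved]))
        series = traj.rmsd_series(ens)
        # the Kabsch fit re-centers, so the naive d/sqrt(N) is an upper bound
        assert series[1] <= d / np.sqrt(50) + 1e-9
        assert series[1] == pytest.approx(d / np.sqrt(50), rel=0.1)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert traj.radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_unit_masses_2A_apart(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert traj.radius_of_gyration(coords) == pytest.approx(1.0, rel=1e-12)

    def test_cube_corners(self):
        corners = np.array([[x, y, z] for x in (0, 2) for y in (0, 2) for z in (0, 2)],
                           dtype=float)
        assert traj.radius_of_gyration(corners) == pytest.approx(np.sqrt(3), rel=1e-12)

    def test_mass_weighting_moves_com(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        rg_unit = traj.radius_of_gyration(coords)
        rg_mass = traj.radius_of_gyration(coords, masses=np.array([1.0, 3.0]))
        assert rg_mass < rg_unit


class TestRmsf:
    def test_static_trajectory_zero(self, rng):
        frame = rng.normal(0, 5, (8, 3))
        ens = toy_ensemble(np.stack([frame] * 5))
        assert (traj.rmsf(ens) < 1e-12).all()

    def test_alternating_atom_closed_form(self):
        base = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4],
                         [4, 4, 0], [4, 0, 4]], dtype=float)
        frames = []
        d = 0.6
        for i in range(10):
            f = base.copy()
            f[0, 0] += d if i % 2 == 0 else -d
            frames.append(f)
        ens = toy_ensemble(np.stack(frames))
        out = traj.rmsf(ens, fit_first=False)
        assert out.loc[1] == pytest.approx(d, rel=1e-12)
        assert out.loc[2] == pytest.approx(0.0, abs=1e-12)

    def test_bfactor_constant(self):
        assert traj.bfactor_from_rmsf(np.array([1.0]))[0] == pytest.approx(
            8 * np.pi ** 2 / 3, rel=1e-12)
        assert traj.bfactor_from_rmsf(np.array([1.0]))[0] == pytest.approx(26.319, abs=1e-3)

    def test_single_frame_rejected(self, rng):
        ens = toy_ensemble(rng.normal(0, 1, (1, 6, 3)))
        with pytest.raises(ValidationError):
            traj.rmsf(ens)


class TestVicinityCounts:
    def _system(self, water_xyz, box=None):
        frames = np.array([[[0.0, 0, 0], *water_xyz]])
        classes = ["protein"] + ["water"] * len(water_xyz)
        resids = [1] + list(range(1, len(water_xyz) + 1))
        return toy_ensemble(frames, classes=classes, resids=resids, box=box)

    def test_closed_boundary_at_cutoff(self):
        inside = self._system([[4.9, 0, 0]])
        outside = self._system([[5.1, 0, 0]])
        at = self._system([[5.0, 0, 0]])
        assert traj.vicinity_counts(inside, 1, "water").counts[0] == 1
        assert traj.vicinity_counts(outside, 1, "water").counts[0] == 0
        assert traj.vicinity_counts(at, 1, "water").counts[0] == 1

    def test_molecule_counted_once(self):
        # one 3-atom molecule with a single atom inside the shell
        frames = np.array([[[0.0, 0, 0], [4.0, 0, 0], [7.0, 0, 0], [9.0, 0, 0]]])
        classes = ["protein", "water", "water", "water"]
        resids = [1, 1, 1, 1]        # all three water atoms share one molecule
        ens = toy_ensemble(frames, classes=classes, resids=resids)
        assert traj.vicinity_counts(ens, 1, "water").counts[0] == 1

    def test_minimum_image_through_boundary(self):
        # direct distance 6 A, but 4 A through the periodic image of a 10 A box
        ens = self._system([[6.0, 0, 0]], box=np.array([[10.0, 10.0, 10.0]]))
        assert traj.vicinity_counts(ens, 1, "water").counts[0] == 1
        no_box = self._system([[6.0, 0, 0]])
        assert traj.vicinity_counts(no_box, 1, "water").counts[0] == 0

    def test_absent_class_rejected(self):
        ens = self._system([[3.0, 0, 0]])
        with pytest.raises(ValidationError):
            traj.vicinity_counts(ens, 1, "detergent")

    def test_matches_brute_force_scan(self):
        """Implementation equals an explicit all-pairs, all-images python scan
        over 100 random toy systems, periodic and not."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            periodic = seed % 2 == 0
            box_edge = 12.0
            n_waters = 15
            pos = rng.uniform(0, box_edge, size=(n_waters, 3))
            probe = rng.uniform(0, box_edge, size=(2, 3))
            frames = np.array([np.vstack([probe, pos])])
            classes = ["protein"] * 2 + ["water"] * n_waters
            resids = [1, 1] + list(range(1, n_waters + 1))
            box = np.array([[box_edge] * 3]) if periodic else None
            ens = toy_ensemble(frames, classes=classes, resids=resids, box=box)
            got = traj.vicinity_counts(ens, 1, "water", cutoff=4.0).counts[0]

            count = 0
            for w in pos:
                near = False
                for p in probe:
                    if periodic:
                        for ix in (-1, 0, 1):
                            for iy in (-1, 0, 1):
                                for iz in (-1, 0, 1):
                                    img = w + box_edge * np.array([ix, iy, iz])
                                    if np.linalg.norm(img - p) <= 4.0:
                                        near = True
                    elif np.linalg.norm(w - p) <= 4.0:
                        near = True
                if near:
                    count += 1
            assert got == count, f"seed {seed}: {got} != {count}"


class TestMicelleFixture:
    def test_solvation_contrast_every_frame(self, micelle):
        """Buried probe: detergent-rich, water-free shell; surface probe the
        inverse — the qualitative buried/exposed solvation inversion."""
        ens, probes = micelle
        det_buried = traj.vicinity_counts(ens, probes["buried_probe"], "detergent").counts
        det_surface = traj.vicinity_counts(ens, probes["surface_probe"], "detergent").counts
        wat_buried = traj.vicinity_counts(ens, probes["buried_probe"], "water").counts
        wat_surface = traj.vicinity_counts(ens, probes["surface_probe"], "water").counts
        assert (det_buried > det_surface).all()
        assert (wat_surface > wat_buried).all()

    def test_metrics_bundle_consistency(self, micelle):
        ens, _ = micelle
        metrics = traj.compute_metrics(ens)
        assert metrics.rmsd.shape == (ens.n_frames,)
        assert metrics.rg.shape == (ens.n_frames,)
        assert metrics.rmsd[0] == pytest.approx(0.0, abs=1e-10)
        assert (metrics.rg > 0).all()
        np.testing.assert_allclose(metrics.bfactor,
                                   8 * np.pi ** 2 / 3 * metrics.rmsf ** 2)
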