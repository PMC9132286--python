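"""Superposition, RMSD, centroid selection and RMSF against independent oracles."""
import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from flexiscreen import (AtomSelection, Ensemble, EnsembleSpec, average_structure,
                         compute_rmsf, generate_ensemble, kabsch_superpose,
                         rmsd_series, select_centroid, superpose_ensemble)
from flexiscreen.errors import DegenerateGeometryError


def _grid_min_rmsd(mobile, reference):
    """Brute-force minimum RMSD over rotation space (coarse grid + local polish)."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def rmsd_of(rotvec):
        r = Rotation.from_rotvec(rotvec).apply(mob)
        return np.sqrt(np.mean(np.sum((r - ref) ** 2, axis=-1)))

    grid = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    candidates = []
    for a in grid:
        for b in grid:
            for c in grid:
                v = Rotation.from_euler("xyz", [a, b, c]).as_rotvec()
                candidates.append((rmsd_of(v), tuple(v)))
    candidates.sort()
    return min(minimize(rmsd_of, np.array(v), method="Nelder-Mead",
                        options={"xatol": 1e-9, "fatol": 1e-13}).fun
               for _, v in candidates[:10])


class TestKabsch:
    def test_self_superposition_is_zero(self, helix12):
        _, r = kabsch_superpose(helix12.coords, helix12.coords)
        assert r == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_is_removed(self, helix12):
        rot = Rotation.from_euler("zyx", [0.7, -1.2, 0.4])
        moved = rot.apply(helix12.coords) + np.array([10.0, -3.0, 2.5])
        transformed, r = kabsch_superpose(moved, helix12.coords)
        assert r == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(transformed, helix12.coords, atol=1e-6)

    def test_matches_rotation_grid_oracle_on_toy_points(self):
        rng = np.random.default_rng(7)
        ref = rng.uniform(-3, 3, (4, 3))
        mob = ref + rng.normal(0, 0.4, (4, 3))
        _, r = kabsch_superpose(mob, ref)
        assert r == pytest.approx(_grid_min_rmsd(mob, ref), abs=1e-3)

    def test_collinear_points_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line + 1.0)

    def test_no_reflection(self):
        """Mirrored coordinates must not be matched exactly (proper rotation only)."""
        rng = np.random.default_rng(1)
        ref = rng.uniform(-2, 2, (6, 3))
        mirrored = ref * np.array([-1.0, 1.0, 1.0])
        _, r = kabsch_superpose(mirrored, ref)
        assert r > 0.1


class TestRmsdSeries:
    def test_copies_of_reference_give_zero_series(self, helix12):
        ens = Ensemble(helix12, np.repeat(helix12.coords[None], 4, axis=0))
        s = rmsd_series(ens, helix12, AtomSelection("all"))
        np.testing.assert_allclose(s.rmsd, 0.0, atol=1e-9)

    def test_pure_translation_gives_zero(self, helix12):
        coords = np.stack([helix12.coords, helix12.coords + np.array([5.0, 0, 0])])
        s = rmsd_series(Ensemble(helix12, coords), helix12, AtomSelection("all"))
        assert s.rmsd[1] == pytest.approx(0.0, abs=1e-9)

    def test_matches_direct_recomputation(self, small_gaussian_ensemble, calpha):
        ens = small_gaussian_ensemble
        ref = ens.frame(0)
        series = rmsd_series(ens, ref, calpha)
        sel = calpha.indices(ens.template)
        # independent recomputation with a hand-rolled SVD Kabsch
        for i in [0, 5, 100]:
            a = ens.coords[i][sel] - ens.coords[i][sel].mean(0)
            b = ref.coords[sel] - ref.coords[sel].mean(0)
            u, s, vt = np.linalg.svd(a.T @ b)
            d = np.sign(np.linalg.det(u @ vt))
            rot = (u @ np.diag([1, 1, d]) @ vt).T
            expect = np.sqrt(np.mean(np.sum((a @ rot.T - b) ** 2, -1)))
            assert series.rmsd[i] == pytest.approx(expect, abs=1e-8)


class TestAverageAndSuperpose:
    def test_average_of_identical_frames_is_the_frame(self, helix12):
        ens = Ensemble(helix12, np.repeat(helix12.coords[None], 3, axis=0))
        np.testing.assert_allclose(average_structure(ens).coords, helix12.coords)

    def test_symmetric_displacements_cancel(self, helix12):
        d = np.full_like(helix12.coords, 0.3)
        ens = Ensemble(helix12, np.stack([helix12.coords + d, helix12.coords - d]))
        np.testing.assert_allclose(average_structure(ens).coords, helix12.coords,
                                   atol=1e-12)

    def test_mean_matches_summation_oracle(self, small_gaussian_ensemble):
        avg = average_structure(small_gaussian_ensemble)
        manual = sum(f.coords for f in small_gaussian_ensemble.frames)
        np.testing.assert_allclose(avg.coords, manual / small_gaussian_ensemble.n_frames,
                                   atol=1e-10)

    def test_aligned_ensemble_is_fixed_point(self, small_gaussian_ensemble, calpha):
        once = superpose_ensemble(small_gaussian_ensemble, calpha)
        twice = superpose_ensemble(once, calpha)
        np.testing.assert_allclose(once.coords, twice.coords, atol=1e-3)

    def test_rigid_copies_collapse_to_identical_frames(self, rigid_copies, calpha):
        aligned = superpose_ensemble(rigid_copies, calpha)
        for i in range(1, aligned.n_frames):
            np.testing.assert_allclose(aligned.coords[i], aligned.coords[0], atol=1e-6)

    def test_total_rmsd_to_average_non_increasing(self, small_gaussian_ensemble, calpha):
        def total(ens):
            avg = ens.coords.mean(axis=0)
            return np.sum((ens.coords - avg) ** 2)
        aligned = superpose_ensemble(small_gaussian_ensemble, AtomSelection("all"))
        assert total(aligned) <= total(small_gaussian_ensemble) + 1e-9

    def test_superposed_rmsd_not_larger_than_unsuperposed(self, small_gaussian_ensemble, calpha):
        ref = small_gaussian_ensemble.frame(0)
        fit = rmsd_series(small_gaussian_ensemble, ref, calpha, superpose=True)
        raw = rmsd_series(small_gaussian_ensemble, ref, calpha, superpose=False)
        assert np.all(fit.rmsd <= raw.rmsd + 1e-9)


class TestCentroid:
    def test_identical_frames_tie_break_to_window_start(self, helix12):
        ens = Ensemble(helix12, np.repeat(helix12.coords[None], 6, axis=0))
        idx, _ = select_centroid(ens, window=(2, 6))
        assert idx == 2

    def test_frame_equal_to_average_is_chosen(self, helix12):
        d = np.full_like(helix12.coords, 0.4)
        coords = np.stack([helix12.coords + d, helix12.coords, helix12.coords - d])
        idx, model = select_centroid(Ensemble(helix12, coords))
        assert idx == 1
        np.testing.assert_allclose(model.coords, helix12.coords)

    def test_matches_exhaustive_scan_oracle(self, calpha):
        ens = generate_ensemble(EnsembleSpec(n_residues=6, n_frames=50,
                                             amplitude_profile=0.4, seed=5))
        aligned = superpose_ensemble(ens, calpha)
        idx, _ = select_centroid(aligned, selection=calpha)
        sel = calpha.indices(aligned.template)
        avg = aligned.coords[:, sel].mean(axis=0)
        scans = []
        for f in range(aligned.n_frames):
            a = aligned.coords[f][sel] - aligned.coords[f][sel].mean(0)
            b = avg - avg.mean(0)
            u, s, vt = np.linalg.svd(a.T @ b)
            d = np.sign(np.linalg.det(u @ vt))
            rot = (u @ np.diag([1, 1, d]) @ vt).T
            scans.append(np.sqrt(np.mean(np.sum((a @ rot.T - b) ** 2, -1))))
        assert idx == int(np.argmin(scans))

    def test_empty_window_rejected(self, helix12):
        ens = Ensemble(helix12, np.repeat(helix12.coords[None], 3, axis=0))
        with pytest.raises(ValueError):
            select_centroid(ens, window=(2, 2))


class TestRmsf:
    def test_identical_frames_give_zero_profile(self, helix12):
        ens = Ensemble(helix12, np.repeat(helix12.coords[None], 5, axis=0))
        profile = compute_rmsf(ens)
        np.testing.assert_allclose(profile.rmsf, 0.0, atol=1e-9)

    def test_two_point_alternation_gives_half_separation(self, helix12):
        """A Cα alternating between two points 2 Å apart has RMSF 1 Å."""
        a = helix12.coords.copy()
        b = helix12.coords.copy()
        ca3 = np.flatnonzero((helix12.names == "CA") & (helix12.res_ids == 3))[0]
        b[ca3] += np.array([2.0, 0.0, 0.0])
        profile = compute_rmsf(Ensemble(helix12, np.stack([a, b])), superpose=False)
        assert profile.value_at(3) == pytest.approx(1.0, abs=1e-12)
        assert profile.value_at(5) == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_closed_form_sigma_sqrt3(self):
        sigma = 0.5
        ens = generate_ensemble(EnsembleSpec(n_residues=8, n_frames=2000,
                                             amplitude_profile=sigma, seed=42))
        profile = compute_rmsf(ens, superpose=False)
        expected = sigma * np.sqrt(3.0)
        np.testing.assert_allclose(profile.rmsf, expected, rtol=0.05)

    def test_invariant_under_global_rigid_motion(self, small_gaussian_ensemble, calpha):
        base = compute_rmsf(small_gaussian_ensemble, calpha)
        rot = Rotation.from_euler("xyz", [1.0, 0.2, -0.5])
        moved = Ensemble(small_gaussian_ensemble.template,
                         rot.apply(small_gaussian_ensemble.coords.reshape(-1, 3)
                                   ).reshape(small_gaussian_ensemble.coords.shape)
                         + np.array([4.0, 5.0, -6.0]))
        again = compute_rmsf(moved, calpha)
        np.testing.assert_allclose(again.rmsf, base.rmsf, rtol=1e-6, atol=1e-8)

    def test_planted_amplitude_ratio_recovered(self):
        """Region-mean RMSF ratio between ensembles recovers the planted 2× contrast."""
        spec = EnsembleSpec(n_residues=12, n_frames=1000, amplitude_profile=0.4, seed=9)
        double = EnsembleSpec(n_residues=12, n_frames=1000, amplitude_profile=0.4,
                              region_scaling={(4, 9): 2.0}, seed=10)
        p1 = compute_rmsf(generate_ensemble(spec), superpose=False)
        p2 = compute_rmsf(generate_ensemble(double), superpose=False)
        ratio = p2.region_mean(4, 9) / p1.region_mean(4, 9)
        assert ratio == pytest.approx(2.0, rel=0.10)
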