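"""Hydrogen-bond detection geometry, occupancy recovery and strength taxonomy."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation
from scipy.stats import binom

from flexiscreen import (Ensemble, EnsembleSpec, FlexibleRegion, HBondCounts,
                         HBondTopology, StructureModel, build_hbond_topology,
                         classify_strength, detect_hbonds_frame,
                         diff_hbond_reports, generate_ensemble, hbond_occupancy,
                         region_hbond_summary)


def _dha_model(d_a_distance, angle_deg):
    """Donor N at origin, H on the x axis, acceptor O at the requested D–A
    distance with the requested D–H⋯A angle at the hydrogen."""
    d = np.zeros(3)
    h = np.array([1.0, 0.0, 0.0])
    dh = 1.0
    theta = np.radians(angle_deg)
    # law of cosines for |HA| given |DA|, |DH| and the angle at H
    r_ha = dh * np.cos(theta) + np.sqrt(
        d_a_distance ** 2 - dh ** 2 * np.sin(theta) ** 2)
    a = h + r_ha * (np.cos(np.pi - theta) * np.array([1.0, 0, 0])
                    + np.sin(np.pi - theta) * np.array([0.0, 1, 0]))
    assert np.linalg.norm(a - d) == pytest.approx(d_a_distance, abs=1e-9)
    m = StructureModel(["N", "H", "O"], ["N", "H", "O"], [1, 1, 2],
                       ["ALA", "ALA", "ALA"], ["A"] * 3, np.stack([d, h, a]))
    return m, HBondTopology(donors=[(0, 1)], acceptors=[0, 2])


class TestDetection:
    @pytest.mark.parametrize("dist,angle,expected", [
        (3.4, 150.0, True),    # inside both criteria
        (3.6, 150.0, False),   # distance fails
        (3.4, 119.0, False),   # angle fails
        (3.5, 120.0, True),    # both boundaries inclusive
        (3.5, 180.0, True),
    ])
    def test_criteria_boundaries(self, dist, angle, expected):
        model, topo = _dha_model(dist, angle)
        obs = detect_hbonds_frame(model, topo)
        assert bool(obs) is expected

    def test_intra_residue_pairs_excluded(self):
        model, _ = _dha_model(3.0, 170.0)
        same_res = StructureModel(model.names, model.elements, [1, 1, 1],
                                  model.res_names, model.chains, model.coords)
        topo = HBondTopology(donors=[(0, 1)], acceptors=[0, 2])
        assert detect_hbonds_frame(same_res, topo) == []

    def test_invariant_under_rigid_motion(self):
        model, topo = _dha_model(3.2, 140.0)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0])
        moved = model.with_coords(rot.apply(model.coords) + np.array([7.0, -2, 3]))
        assert len(detect_hbonds_frame(moved, topo)) == \
            len(detect_hbonds_frame(model, topo))


class TestOccupancy:
    def test_planted_exact_occupancies(self):
        spec = EnsembleSpec(n_residues=12, n_frames=100, amplitude_profile=0.05,
                            planted_hbonds=((2, 9, 100.0), (3, 10, 60.0)), seed=1)
        ens = generate_ensemble(spec)
        topo = build_hbond_topology(ens.frame(0))
        stats = hbond_occupancy(ens, topo)
        by_pair = {(s.donor_residue, s.acceptor_residue): s.occupancy
                   for s in stats}
        assert by_pair[(2, 9)] == pytest.approx(100.0)
        assert by_pair[(3, 10)] == pytest.approx(60.0)

    def test_bernoulli_occupancy_within_99_ci(self):
        p = 0.4
        n = 1000
        spec = EnsembleSpec(n_residues=10, n_frames=n, amplitude_profile=0.05,
                            planted_hbonds=((2, 8, 100 * p),), seed=7,
                            exact_occupancy=False)
        ens = generate_ensemble(spec)
        stats = hbond_occupancy(ens, build_hbond_topology(ens.frame(0)))
        occ = {(s.donor_residue, s.acceptor_residue): s.occupancy
               for s in stats}[(2, 8)]
        lo, hi = binom.ppf([0.005, 0.995], n, p) / n * 100
        assert lo <= occ <= hi

    def test_stable_under_frame_reordering(self):
        spec = EnsembleSpec(n_residues=10, n_frames=50, amplitude_profile=0.05,
                            planted_hbonds=((2, 8, 40.0),), seed=3)
        ens = generate_ensemble(spec)
        topo = build_hbond_topology(ens.frame(0))
        shuffled = Ensemble(ens.template,
                            ens.coords[np.random.default_rng(0).permutation(50)])
        a = {(s.donor_residue, s.acceptor_residue): s.occupancy
             for s in hbond_occupancy(ens, topo)}
        b = {(s.donor_residue, s.acceptor_residue): s.occupancy
             for s in hbond_occupancy(shuffled, topo)}
        assert a == b

    def test_zero_frames_rejected(self):
        spec = EnsembleSpec(n_residues=6, n_frames=5, amplitude_profile=0.05, seed=0)
        ens = generate_ensemble(spec)
        with pytest.raises(ValueError):
            hbond_occupancy(ens, build_hbond_topology(ens.frame(0)), window=(2, 2))


class TestStrength:
    @pytest.mark.parametrize("occ,expected", [
        (80.0, "strong"), (75.0, "medium"), (50.0, "weak"),
        (25.0, "very_weak"), (10.0, "unreported"), (0.0, "unreported"),
        (100.0, "strong"), (10.0001, "very_weak"),
    ])
    def test_published_bin_boundaries(self, occ, expected):
        assert classify_strength(occ) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_strength(101.0)
        with pytest.raises(ValueError):
            classify_strength(-0.1)

    @given(st.floats(0, 100, allow_nan=False))
    def test_bins_partition_without_gaps(self, occ):
        cls = classify_strength(occ)
        assert cls in ("strong", "medium", "weak", "very_weak", "unreported")
        if occ > 10.0:
            assert cls != "unreported"
        else:
            assert cls == "unreported"


def _stat(donor_res, acceptor_res, occ, idx=0):
    from flexiscreen.hbonds import HBondStat
    return HBondStat(idx * 2, idx * 2 + 1, donor_res, acceptor_res,
                     "N", "O", occ, classify_strength(occ))


class TestRegionSummaryAndDiff:
    region = FlexibleRegion(4, 201, 214)

    def test_empty_stats_give_zero_counts(self):
        counts = region_hbond_summary([], self.region)
        assert counts.as_tuple() == (0, 0, 0, 0)

    def test_planted_strength_mixture(self):
        stats = [_stat(205, 300, 80.0, 0), _stat(210, 301, 60.0, 1),
                 _stat(302, 207, 30.0, 2), _stat(400, 401, 90.0, 3)]
        counts = region_hbond_summary(stats, self.region)
        assert counts.as_tuple() == (1, 1, 1, 0)

    def test_unreported_bonds_not_counted(self):
        stats = [_stat(205, 300, 5.0)]
        assert region_hbond_summary(stats, self.region).total == 0

    def test_differential_planted_bond(self):
        wt = generate_ensemble(EnsembleSpec(
            n_residues=16, n_frames=60, amplitude_profile=0.05,
            base_geometry="strand", planted_hbonds=((5, 12, 60.0),), seed=5))
        mut = generate_ensemble(EnsembleSpec(
            n_residues=16, n_frames=60, amplitude_profile=0.05,
            base_geometry="strand",
            planted_hbonds=((5, 12, 60.0), (6, 13, 90.0)), seed=5))
        topo = build_hbond_topology(wt.frame(0))
        region = FlexibleRegion(1, 4, 8)
        wt_counts = region_hbond_summary(hbond_occupancy(wt, topo), region)
        mut_counts = region_hbond_summary(hbond_occupancy(mut, topo), region)
        assert mut_counts.strong - wt_counts.strong == 1

    def test_published_region4_deltas(self):
        wt = HBondCounts(4, 0, 0, 3, 21)
        mut = HBondCounts(4, 1, 3, 9, 17)
        deltas = diff_hbond_reports(wt, mut)
        assert deltas == {"strong": 1, "medium": 3, "weak": 6,
                          "very_weak": -4, "total": 6}

    def test_diff_antisymmetry(self):
        a = HBondCounts(1, 2, 3, 4, 5)
        b = HBondCounts(1, 1, 1, 1, 1)
        fwd = diff_hbond_reports(a, b)
        rev = diff_hbond_reports(b, a)
        assert all(fwd[k] == -rev[k] for k in fwd)

    def test_region_mismatch_rejected(self):
        with pytest.raises(ValueError):
            diff_hbond_reports(HBondCounts(1), HBondCounts(2))
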