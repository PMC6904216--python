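"""Helix geometry: torsions, helicity, axes, hydration, RMSD, contacts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from vsdkit.core import MembraneFrame, ResidueSelection
from vsdkit.geometry import (
    HelicityParams, TorsionRecord, bend_angle, compute_torsions,
    contact_persistence, helicity, helicity_profile, hydration_profile,
    principal_axis, rmsd_to_reference,
)
from vsdkit.synthetic import make_helix, make_hinged_helix, make_water_box

from conftest import point_frame

PARAMS = HelicityParams()


class TestTorsions:
    def test_ideal_helix_reproduces_generator_torsions(self, helix20,
                                                       helix20_selection):
        records = compute_torsions(helix20, helix20_selection)[0]
        for rec in records:
            if rec.defined:
                assert rec.phi == pytest.approx(-57.0, abs=1.0)
                assert rec.psi == pytest.approx(-47.0, abs=1.0)

    def test_termini_flagged_undefined_not_dropped(self, helix20,
                                                   helix20_selection):
        records = compute_torsions(helix20, helix20_selection)[0]
        assert len(records) == 20
        assert math.isnan(records[0].phi) and not math.isnan(records[0].psi)
        assert math.isnan(records[-1].psi) and not math.isnan(records[-1].phi)

    def test_three_residue_chain_has_one_defined_pair(self):
        helix = make_helix(4)
        sel = ResidueSelection("A", [1, 2, 3, 4])
        records = compute_torsions(helix, sel)[0]
        assert not records[0].defined and not records[-1].defined
        assert records[1].defined and records[2].defined

    def test_mirror_image_flips_torsion_signs(self, helix20, helix20_selection):
        mirror = helix20.translated([0, 0, 0])
        mirror.coordinates = helix20.coordinates * np.array([1.0, 1.0, -1.0])
        orig = compute_torsions(helix20, helix20_selection)[0]
        flip = compute_torsions(mirror, helix20_selection)[0]
        for a, b in zip(orig, flip):
            if a.defined:
                assert b.phi == pytest.approx(-a.phi, abs=1e-9)
                assert b.psi == pytest.approx(-a.psi, abs=1e-9)


class TestHelicity:
    @pytest.mark.parametrize("phi,psi,expected", [
        (PARAMS.phi_alpha, PARAMS.psi_alpha, 1.0),
        (PARAMS.phi_alpha + 180.0, PARAMS.psi_alpha + 180.0, 0.0),
        (PARAMS.phi_alpha + 90.0, PARAMS.psi_alpha, 0.5),
    ])
    def test_closed_forms(self, phi, psi, expected):
        assert helicity(TorsionRecord(1, phi, psi)) == pytest.approx(expected,
                                                                     abs=1e-12)

    def test_undefined_torsion_gives_nan(self):
        assert math.isnan(helicity(TorsionRecord(1, float("nan"), -47.0)))

    @settings(max_examples=200, deadline=None)
    @given(phi=st.floats(-179.999, 180.0), psi=st.floats(-179.999, 180.0))
    def test_bounded_on_any_angles(self, phi, psi):
        h = helicity(TorsionRecord(1, phi, psi))
        assert 0.0 <= h <= 1.0

    def test_ideal_helix_profile_near_one(self, helix20, helix20_selection):
        table = helicity_profile(helix20, helix20_selection)
        interior = table.dropna()
        assert (interior["hp"] >= 0.99).all()


class TestAxes:
    def test_straight_helix_axis_is_z(self, helix20, helix20_selection):
        axis = principal_axis(helix20, helix20_selection)
        assert axis @ np.array([0.0, 0.0, 1.0]) == pytest.approx(1.0, abs=1e-3)

    def test_rotated_helix_axis_rotates_with_it(self, helix20, helix20_selection):
        rot = Rotation.from_euler("x", 30, degrees=True)
        axis0 = principal_axis(helix20, helix20_selection)
        rotated = helix20.translated([0, 0, 0])
        rotated.coordinates = rot.apply(helix20.coordinates)
        axis1 = principal_axis(rotated, helix20_selection,
                               normal=tuple(rot.apply([0.0, 0.0, 1.0])))
        np.testing.assert_allclose(axis1, rot.apply(axis0), atol=1e-6)

    def test_isotropic_cloud_is_degenerate(self):
        # vertices of a regular octahedron: perfectly isotropic covariance
        pts = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                        [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
        frame = point_frame(pts, names=["CA"] * 6)
        with pytest.raises(ValueError, match="degenerate"):
            principal_axis(frame, ResidueSelection("A", range(1, 7)))

    @pytest.mark.parametrize("true_bend", [0.0, 30.0, 80.0, 90.0])
    def test_hinged_helix_recovers_generator_angle(self, true_bend):
        helix = make_hinged_helix(40, 20, true_bend)
        upper = ResidueSelection("A", range(21, 41))
        lower = ResidueSelection("A", range(1, 20))
        ref = principal_axis(helix, upper)
        assert bend_angle(helix, lower, ref) == pytest.approx(true_bend, abs=3.0)

    def test_bend_angle_parallel_and_perpendicular(self, helix20):
        sub = ResidueSelection("A", range(1, 21))
        assert bend_angle(helix20, sub, [0, 0, 1]) == pytest.approx(0.0, abs=1.0)
        ang = bend_angle(helix20, sub, [1, 0, 0])
        assert ang == pytest.approx(90.0, abs=1.0)

    def test_bend_angle_invariant_under_joint_rigid_motion(self):
        helix = make_hinged_helix(36, 18, 80.0)
        lower = ResidueSelection("A", range(1, 18))
        ref = np.array([0.0, 0.0, 1.0])
        before = bend_angle(helix, lower, ref)
        rot = Rotation.from_euler("zyx", [14, 65, -40], degrees=True)
        moved = helix.translated([0, 0, 0])
        moved.coordinates = rot.apply(helix.coordinates) + np.array([5, 6, 7.0])
        moved_normal = rot.apply([0.0, 0.0, 1.0])
        after = bend_angle(moved, lower, rot.apply(ref),
                           normal=tuple(moved_normal))
        assert after == pytest.approx(before, abs=1e-6)


class TestHydration:
    def test_single_bin_counts(self):
        waters = make_water_box([0, 0, 10], [10, 10, 12], 10, seed=1)
        sel = ResidueSelection("W", range(1, 11))
        mframe = MembraneFrame()
        prof = hydration_profile(waters, sel, mframe, bin_width=3.0,
                                 z_range=(9.0, 15.0))
        assert prof.counts.sum() == 10
        assert prof.counts[0, 0] == 10

    def test_identical_frames_have_equal_percentiles(self):
        waters = make_water_box([0, 0, 0], [10, 10, 30], 50, seed=2)
        sel = ResidueSelection("W", range(1, 51))
        prof = hydration_profile([waters] * 5, sel, MembraneFrame(),
                                 bin_width=3.0)
        for col in ("p10", "p25", "p50", "p75", "p90"):
            np.testing.assert_array_equal(prof.percentiles[col],
                                          prof.percentiles["p50"])

    def test_uniform_waters_match_direct_histogram(self):
        waters = make_water_box([0, 0, 0], [10, 10, 30], 300, seed=3)
        sel = ResidueSelection("W", range(1, 301))
        prof = hydration_profile(waters, sel, MembraneFrame(), bin_width=3.0,
                                 z_range=(0.0, 30.0))
        z = waters.coordinates[:, 2]
        expected = np.histogram(z, bins=prof.bin_edges)[0]
        np.testing.assert_array_equal(prof.counts[0], expected)
        assert prof.counts[0].mean() == pytest.approx(30.0, rel=0.25)

    def test_median_matches_naive_sort_oracle(self):
        frames = [make_water_box([0, 0, 0], [10, 10, 30], 100, seed=s)
                  for s in range(7)]
        sel = ResidueSelection("W", range(1, 101))
        prof = hydration_profile(frames, sel, MembraneFrame(), bin_width=3.0,
                                 z_range=(0.0, 30.0))
        for b in range(prof.counts.shape[1]):
            vals = sorted(prof.counts[:, b])
            assert prof.percentiles["p50"][b] == pytest.approx(vals[3])

    def test_empty_frame_set_rejected(self):
        sel = ResidueSelection("W", [1])
        with pytest.raises(ValueError):
            hydration_profile([], sel, MembraneFrame(), bin_width=3.0)


class TestRmsd:
    def test_self_rmsd_zero(self, helix20, helix20_selection):
        assert rmsd_to_reference(helix20, helix20, helix20_selection) == \
            pytest.approx(0.0, abs=1e-12)
        assert rmsd_to_reference(helix20, helix20, helix20_selection,
                                 superpose=False) == 0.0

    def test_rotated_copy_superposes_to_zero(self, helix20, helix20_selection):
        rot = Rotation.from_euler("xyz", [10, 20, 30], degrees=True)
        moved = helix20.translated([0, 0, 0])
        moved.coordinates = rot.apply(helix20.coordinates) + np.array([1, 2, 3.0])
        assert rmsd_to_reference(moved, helix20, helix20_selection,
                                 superpose=True) == pytest.approx(0.0, abs=1e-6)

    def test_single_displaced_atom_closed_form(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 20, size=(100, 3))
        frame = point_frame(coords, names=["CA"] * 100)
        moved = frame.translated([0, 0, 0])
        moved.coordinates = coords.copy()
        moved.coordinates[0] += [2.0, 0.0, 0.0]
        sel = ResidueSelection("A", range(1, 101))
        assert rmsd_to_reference(moved, frame, sel,
                                 superpose=False) == pytest.approx(0.2)

    def test_atom_mismatch_lists_residues(self, helix20):
        sel_a = ResidueSelection("A", range(1, 21))
        reduced = helix20.subset(~helix20.atom_mask(residue_indices=[7],
                                                    atom_names=["O"]))
        with pytest.raises(ValueError, match="7"):
            rmsd_to_reference(reduced, helix20, sel_a)


class TestContacts:
    def make_pair_frames(self, separations):
        frames = []
        for d in separations:
            frames.append(point_frame([[0, 0, 0], [0, 0, d]],
                                      resids=[1, 2], names=["CA", "CA"]))
        return frames

    def test_always_in_contact(self):
        frames = self.make_pair_frames([3.0] * 10)
        recs = contact_persistence(frames, ResidueSelection("A", [1]),
                                   ResidueSelection("A", [2]), cutoff=4.5)
        assert len(recs) == 1 and recs[0].persistence == 1.0

    def test_never_in_contact_absent_or_zero(self):
        frames = self.make_pair_frames([9.0] * 4)
        a, b = ResidueSelection("A", [1]), ResidueSelection("A", [2])
        assert contact_persistence(frames, a, b, cutoff=4.5) == []
        recs = contact_persistence(frames, a, b, cutoff=4.5,
                                   include_absent=True)
        assert len(recs) == 1 and recs[0].persistence == 0.0

    def test_partial_contact_matches_brute_force(self):
        seps = [3.0] * 7 + [9.0] * 3
        frames = self.make_pair_frames(seps)
        recs = contact_persistence(frames, ResidueSelection("A", [1]),
                                   ResidueSelection("A", [2]), cutoff=4.5)
        brute = np.mean([d <= 4.5 for d in seps])
        assert recs[0].persistence == pytest.approx(brute)
        assert recs[0].persistence == pytest.approx(0.7)

    def test_hydrogens_ignored(self):
        frame = point_frame([[0, 0, 0], [0, 0, 3.0]], resids=[1, 2],
                            elements=["C", "H"], names=["CA", "H1"])
        with pytest.raises(ValueError, match="empty heavy-atom"):
            contact_persistence([frame], ResidueSelection("A", [1]),
                                ResidueSelection("A", [2]), cutoff=4.5)
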