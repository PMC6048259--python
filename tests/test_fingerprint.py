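import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.spatial.transform import Rotation

from deltabind import (
    build_toy_dimer,
    contact_difference,
    contact_map,
    detect_hbonds,
    hbond_count_significance,
    hbr_table,
    native_contact_fraction,
    reference_contacts,
    residue_com,
    rmsd,
    rmsf,
    subsample,
)
from deltabind.fingerprint import round_ratio
from deltabind.trajectory import TrajectoryEnsemble


def as_traj(frames):
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    return TrajectoryEnsemble(
        coords=frames, frame_potential=np.zeros(n), frame_boost=np.zeros(n)
    )


class TestResidueCom:
    def test_single_bead_residue_is_its_position(self):
        system = build_toy_dimer(1, 1, "WT", 0)
        lig = int(system.ligand_residues[0])
        beads = system.residue_beads(lig)
        if len(beads) == 1:
            np.testing.assert_allclose(
                residue_com(system, system.bead_positions, lig),
                system.bead_positions[beads[0]],
            )

    def test_matches_hand_mass_weighted_mean(self, wt_system, rng):
        coords = rng.normal(0, 5, (wt_system.n_beads, 3))
        for res in range(wt_system.n_residues):
            beads = wt_system.residue_beads(res)
            m = wt_system.bead_masses[beads]
            expected = (m[:, None] * coords[beads]).sum(axis=0) / m.sum()
            np.testing.assert_allclose(
                residue_com(wt_system, coords, res), expected, atol=1e-12
            )

    def test_two_equal_mass_beads_give_midpoint(self):
        from deltabind.toysys import ToySystem

        system = ToySystem(
            bead_positions=np.array([[0.0, 0, 0], [2.0, 0, 0]]),
            bead_masses=np.array([5.0, 5.0]),
            bead_charges=np.zeros(2),
            bead_radii=np.ones(2),
            bead_names=["CA", "SB"],
            residue_ids=np.array([0, 0]),
            residue_names=["R01"],
            chain_ids=["A"],
            bonds=np.zeros((0, 2), dtype=int),
            bond_params=np.zeros((0, 2)),
            eps=np.zeros((2, 2)),
            sigma=np.ones((2, 2)),
            nb_mask=np.zeros((2, 2), dtype=bool),
            hbond_sites=[],
        )
        np.testing.assert_allclose(
            residue_com(system, system.bead_positions, 0), [1.0, 0, 0]
        )


class TestContactMap:
    def test_boundary_is_inclusive_at_six_angstroms(self, wt_system):
        # place ligand residue 0 COM at exactly 5.9 then 6.1 A from receptor 0
        rec = int(wt_system.receptor_residues[0])
        lig = int(wt_system.ligand_residues[0])
        lig_beads = wt_system.residue_beads(lig)
        for dist, expected in ((5.9, 1.0), (6.1, 0.0)):
            coords = wt_system.bead_positions.copy()
            rc = residue_com(wt_system, coords, rec)
            lc = residue_com(wt_system, coords, lig)
            goal = rc + np.array([0.0, dist, 0.0])
            coords[lig_beads] += goal - lc
            traj = as_traj([coords])
            cm = contact_map(traj, wt_system)
            assert cm.frequencies[0, 0] == expected

    def test_difference_map_basics(self, wt_system):
        traj = as_traj([wt_system.bead_positions])
        a = contact_map(traj, wt_system)
        assert np.all(contact_difference(a, a) == 0.0)

    @given(
        hnp.arrays(float, (3, 4), elements=st.floats(0, 1)),
        hnp.arrays(float, (3, 4), elements=st.floats(0, 1)),
    )
    @settings(max_examples=30, deadline=None)
    def test_difference_map_antisymmetry(self, a, b):
        from deltabind.fingerprint import ContactMap

        ca = ContactMap(a, np.arange(3), np.arange(4), 6.0, 1)
        cb = ContactMap(b, np.arange(3), np.arange(4), 6.0, 1)
        np.testing.assert_allclose(
            contact_difference(ca, cb), -contact_difference(cb, ca)
        )


class TestDetectHbonds:
    def place(self, system, d_da, angle_deg):
        """Put acceptor 0 at distance d_da from donor 0 with the given
        acceptor-H-donor angle; move the rest of the ligand far away."""
        coords = system.bead_positions.copy()
        donor, hydrogen, acceptors = system.hbond_sites[0]
        lig_beads = np.concatenate(
            [system.residue_beads(int(r)) for r in system.ligand_residues]
        )
        coords[lig_beads] += [0.0, 50.0, 0.0]
        d_pos = coords[donor]
        u = coords[hydrogen] - d_pos
        u /= np.linalg.norm(u)
        r_dh = np.linalg.norm(coords[hydrogen] - d_pos)
        phi = np.radians(angle_deg)
        v = np.array([1.0, 0.0, 0.0])
        v -= (v @ u) * u
        v /= np.linalg.norm(v)
        # solve |HA| so that |DA| = d_da for the chosen angle at H
        # |DA|^2 = r_dh^2 + a^2 - 2 r_dh a cos(phi)
        coeffs = [1.0, -2 * r_dh * np.cos(phi), r_dh**2 - d_da**2]
        a = max(np.roots(coeffs).real)
        direction = np.cos(phi) * (-u) + np.sin(phi) * v
        coords[acceptors[0]] = coords[hydrogen] + a * direction
        return coords

    def test_geometric_criterion_cases(self, wt_system):
        cases = [
            (2.9, 180.0, 1),  # linear, short: a bond
            (2.9, 120.0, 0),  # short but bent: no bond
            (3.1, 180.0, 0),  # linear but long: no bond
            (2.9999, 135.01, 1),  # just inside the inclusive boundaries
        ]
        for d, ang, expected in cases:
            coords = self.place(wt_system, d, ang)
            recs = [
                r
                for r in detect_hbonds(wt_system, coords)
                if r.acceptor == wt_system.hbond_sites[0][2][0]
                and r.donor == wt_system.hbond_sites[0][0]
            ]
            assert len(recs) == expected, (d, ang)
            if expected:
                assert recs[0].distance == pytest.approx(d, abs=1e-9)
                assert recs[0].angle == pytest.approx(ang, abs=1e-6)


class TestSubsample:
    def test_every_tenth_of_45000_gives_4500(self):
        idx = subsample(np.arange(45_000), 10)
        assert len(idx) == 4_500
        assert idx[0] == 0 and idx[1] == 10

    def test_stride_one_is_identity(self):
        np.testing.assert_array_equal(subsample(np.arange(7), 1), np.arange(7))

    def test_small_example(self):
        np.testing.assert_array_equal(subsample(np.arange(7), 3), [0, 3, 6])

    @given(st.integers(1, 2000), st.integers(1, 7), st.integers(1, 7))
    @settings(max_examples=50, deadline=None)
    def test_composition_property(self, n, a, b):
        x = np.arange(n)
        np.testing.assert_array_equal(
            subsample(subsample(x, a), b), subsample(x, a * b)
        )
        assert len(subsample(x, a)) == int(np.ceil(n / a))


class TestHbrTable:
    def test_printed_reference_rows(self):
        table = hbr_table(
            {"D277-S279": 13, "D262-W489": 28},
            {"D277-S279": 37, "D262-W489": 57},
            {"D277-S279": 0, "D262-W489": 48},
            {"D277-S279": 0, "D262-W489": 18},
        )
        row = table[table.pair == "D277-S279"].iloc[0]
        assert row.hbr1_display == 2.85 and row.hbr2_display == 0.0
        assert row.flag == "Yes"
        row = table[table.pair == "D262-W489"].iloc[0]
        assert row.hbr1_display == 2.04 and row.hbr2_display == 0.37
        assert row.flag == "Yes"

    def test_all_zero_counts_are_indeterminate(self):
        table = hbr_table({"X-Y": 0}, {"X-Y": 0}, {"X-Y": 0}, {"X-Y": 0})
        row = table.iloc[0]
        assert row.hbr1 == 0.0 and row.hbr2 == 0.0 and row.flag == "-"

    def test_three_decimal_escalation_for_colliding_ratios(self):
        table = hbr_table(
            {"E457-K263": 79}, {"E457-K263": 74}, {"E457-K263": 124}, {"E457-K263": 116}
        )
        row = table.iloc[0]
        assert row.display_decimals == 3
        assert row.hbr1_display == 0.937 and row.hbr2_display == 0.935
        assert row.flag == "Yes"

    def test_tie_rounding_is_half_down(self):
        assert round_ratio(18, 48) == 0.37  # 0.375 resolves downward
        assert round_ratio(75, 53) == 1.42
        assert round_ratio(5, 37) == 0.14

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hbr_table({"X-Y": -1}, {"X-Y": 0}, {"X-Y": 0}, {"X-Y": 0})


class TestHbondSignificance:
    def test_identical_arrays_give_p_one(self):
        a = np.arange(100) % 4
        assert hbond_count_significance(a, a) == 1.0

    def test_shifted_distributions_detected(self, rng):
        a = rng.poisson(6.0, 5000)
        b = rng.poisson(4.0, 5000)
        assert hbond_count_significance(a, b) < 1e-3

    def test_null_calibration(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(200):
            a = rng.poisson(5.0, 400)
            b = rng.poisson(5.0, 400)
            ps.append(hbond_count_significance(a, b))
        assert 0.005 < np.mean(np.asarray(ps) < 0.05) < 0.12


class TestRmsd:
    def test_identical_coordinates_give_zero(self, rng):
        x = rng.normal(0, 3, (10, 3))
        assert rmsd(x, x) == pytest.approx(0.0, abs=1e-10)

    def test_rigid_transform_invariance(self, rng):
        x = rng.normal(0, 3, (12, 3))
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7])
        y = rot.apply(x) + np.array([5.0, -2.0, 9.0])
        assert rmsd(y, x) == pytest.approx(0.0, abs=1e-8)
        assert rmsd(x, y) == pytest.approx(rmsd(y, x), abs=1e-8)

    def test_matches_brute_force_rotation_grid_on_four_beads(self, rng):
        x = rng.normal(0, 2, (4, 3))
        y = x.copy()
        y[0] += [1.0, 0.5, -0.3]
        fitted = rmsd(y, x)
        # independent oracle: coarse random rotation search refined by a
        # generic optimiser over the rotation vector (no Kabsch involved)
        from scipy.optimize import minimize

        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)

        def objective(rotvec):
            d = Rotation.from_rotvec(rotvec).apply(yc) - xc
            return np.sqrt(np.mean(np.sum(d * d, axis=1)))

        best_start, best_val = None, np.inf
        for rot in Rotation.random(500, rng=np.random.default_rng(0)):
            val = objective(rot.as_rotvec())
            if val < best_val:
                best_start, best_val = rot.as_rotvec(), val
        res = minimize(objective, best_start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        assert fitted <= res.fun + 1e-8  # superposition is optimal
        assert fitted == pytest.approx(res.fun, abs=1e-5)


class TestRmsf:
    def test_static_trajectory_gives_zero_everywhere(self, wt_system):
        traj = as_traj([wt_system.bead_positions] * 5)
        table = rmsf(traj, wt_system)
        assert np.allclose(table["rmsf"], 0.0, atol=1e-10)

    def test_isotropic_jitter_recovers_sigma_sqrt3(self):
        system = build_toy_dimer(10, 10, "WT", 0)
        rng = np.random.default_rng(12)
        sigma = 0.25
        frames = system.bead_positions[None] + rng.normal(
            0, sigma, (10_000, system.n_beads, 3)
        )
        table = rmsf(as_traj(frames), system)
        expected = sigma * np.sqrt(3.0)
        assert np.mean(table["rmsf"]) == pytest.approx(expected, rel=0.05)

    def test_invariant_to_rigid_body_motion_of_frames(self, wt_system, rng):
        base = wt_system.bead_positions
        frames = base[None] + rng.normal(0, 0.1, (50, wt_system.n_beads, 3))
        moved = []
        for f in frames:
            rot = Rotation.from_rotvec(rng.normal(0, 0.5, 3))
            moved.append(rot.apply(f) + rng.normal(0, 5.0, 3))
        a = rmsf(as_traj(frames), wt_system)["rmsf"].to_numpy()
        b = rmsf(as_traj(np.array(moved)), wt_system)["rmsf"].to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-8)


class TestNativeContacts:
    def test_reference_frame_scores_one(self, wt_system):
        ref = reference_contacts(wt_system)
        assert ref, "bound reference must have contacts"
        assert native_contact_fraction(wt_system.bead_positions, wt_system, ref) == 1.0

    def test_dissociated_frame_scores_zero(self, wt_system):
        ref = reference_contacts(wt_system)
        coords = wt_system.dissociated_positions()
        assert native_contact_fraction(coords, wt_system, ref) == 0.0

    def test_half_broken_by_construction(self, wt_system):
        ref = reference_contacts(wt_system)
        keep = ref[: len(ref) // 2]
        broken = ref[len(ref) // 2 :]
        coords = wt_system.bead_positions.copy()
        moved = {rj for _, rj in broken} - {rj for _, rj in keep}
        # displace only ligand residues whose every reference pair is broken
        target = [
            (ri, rj) for (ri, rj) in ref if rj not in moved
        ]
        for rj in moved:
            coords[wt_system.residue_beads(rj)] += [0.0, 40.0, 0.0]
        q = native_contact_fraction(coords, wt_system, ref)
        assert q == pytest.approx(len(target) / len(ref))
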