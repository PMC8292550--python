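import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from interkit.contacts import (
    ContactSite,
    Frame,
    Trajectory,
    aggregate_sites,
    classify_stability,
    electrostatic_score,
    flag_contacts,
    score_sites,
)
from interkit.errors import InvalidParameterError
from interkit.synthetic import PlantedContact, PlantedInterface, generate_toy_complex


def brute_force_flags(frame, cutoff=3.0, min_atoms=3):
    """Independent oracle: full O(N^2) distance matrix, no spatial tree."""
    mask_a = frame.molecule_tags == "A"
    mask_b = frame.molecule_tags == "B"
    ia = np.flatnonzero(mask_a)
    ib = np.flatnonzero(mask_b)
    d = np.linalg.norm(
        frame.positions[ia][:, None, :] - frame.positions[ib][None, :, :], axis=-1
    )
    flagged = set()
    res_a = sorted(set(frame.residue_numbers[ia].tolist()))
    res_b = sorted(set(frame.residue_numbers[ib].tolist()))
    for ra in res_a:
        sel_a = frame.residue_numbers[ia] == ra
        for rb in res_b:
            sel_b = frame.residue_numbers[ib] == rb
            sub = d[np.ix_(sel_a, sel_b)] <= cutoff
            n_a = int(np.sum(sub.any(axis=1)))
            n_b = int(np.sum(sub.any(axis=0)))
            if n_a >= min_atoms or n_b >= min_atoms:
                flagged.add((ra, rb))
    return flagged


def random_frame(rng, n_atoms=200, box=15.0):
    half = n_atoms // 2
    return Frame(
        positions=rng.uniform(0, box, (n_atoms, 3)),
        residue_names=np.full(n_atoms, "ALA"),
        residue_numbers=np.concatenate(
            [rng.integers(1, 11, half), rng.integers(1, 11, n_atoms - half)]
        ),
        molecule_tags=np.array(["A"] * half + ["B"] * (n_atoms - half)),
    )


class TestFlagContacts:
    def test_separated_chains_yield_nothing(self):
        iface = PlantedInterface(contacts=())
        traj, _ = generate_toy_complex(iface, n_frames=1)
        assert flag_contacts(traj[0]) == []

    def test_three_atoms_at_boundary_flagged(self):
        iface = PlantedInterface(
            contacts=(PlantedContact(residue_a=3, residue_b=4, n_atoms_close=3,
                                     target_distance=2.9),)
        )
        traj, _ = generate_toy_complex(iface, n_frames=1)
        pairs = flag_contacts(traj[0], cutoff=3.0, min_atoms=3)
        assert [(p.residue_a[1], p.residue_b[1]) for p in pairs] == [(3, 4)]

    def test_two_atoms_not_flagged(self):
        iface = PlantedInterface(
            contacts=(PlantedContact(residue_a=3, residue_b=4, n_atoms_close=2,
                                     target_distance=2.9),)
        )
        traj, _ = generate_toy_complex(iface, n_frames=1)
        assert flag_contacts(traj[0], cutoff=3.0, min_atoms=3) == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            frame = random_frame(rng)
            got = {
                (p.residue_a[1], p.residue_b[1]) for p in flag_contacts(frame)
            }
            assert got == brute_force_flags(frame)

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(7)
        frame = random_frame(rng)
        prev = set()
        for cutoff in (2.0, 3.0, 4.0, 6.0):
            cur = {
                (p.residue_a[1], p.residue_b[1])
                for p in flag_contacts(frame, cutoff=cutoff)
            }
            assert prev <= cur
            prev = cur

    def test_min_atoms_monotonicity(self):
        rng = np.random.default_rng(8)
        frame = random_frame(rng)
        prev = None
        for min_atoms in (1, 2, 3, 5):
            cur = {
                (p.residue_a[1], p.residue_b[1])
                for p in flag_contacts(frame, cutoff=5.0, min_atoms=min_atoms)
            }
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(9)
        frame = random_frame(rng)
        rot = Rotation.random(rng=42).as_matrix()
        shift = np.array([10.0, -5.0, 3.0])
        moved = Frame(
            positions=frame.positions @ rot.T + shift,
            residue_names=frame.residue_names,
            residue_numbers=frame.residue_numbers,
            molecule_tags=frame.molecule_tags,
        )
        same = lambda f: {
            (p.residue_a[1], p.residue_b[1]) for p in flag_contacts(f)
        }
        assert same(frame) == same(moved)

    def test_triggering_side_recorded(self):
        iface = PlantedInterface(
            contacts=(PlantedContact(residue_a=2, residue_b=2, n_atoms_close=3,
                                     target_distance=2.5),)
        )
        traj, _ = generate_toy_complex(iface, n_frames=1)
        (pair,) = flag_contacts(traj[0])
        assert pair.triggered_by in ("A", "B", "AB")
        assert pair.n_atoms_a >= 3 or pair.n_atoms_b >= 3

    def test_single_molecule_frame_raises(self):
        frame = Frame(
            positions=np.zeros((3, 3)) + np.arange(3)[:, None],
            residue_names=np.full(3, "ALA"),
            residue_numbers=np.array([1, 1, 1]),
            molecule_tags=np.array(["A", "A", "A"]),
        )
        with pytest.raises(InvalidParameterError):
            flag_contacts(frame)

    def test_nonpositive_cutoff_raises(self):
        iface = PlantedInterface()
        traj, _ = generate_toy_complex(iface, n_frames=1)
        with pytest.raises(InvalidParameterError):
            flag_contacts(traj[0], cutoff=-1.0)


class TestAggregateSites:
    def test_always_flagged_has_occupancy_one(self):
        iface = PlantedInterface(
            contacts=(PlantedContact(residue_a=2, residue_b=3, occupancy=1.0),)
        )
        traj, _ = generate_toy_complex(iface, n_frames=10)
        sites = aggregate_sites(traj)
        assert len(sites) == 1
        assert sites[0].occupancy == 1.0

    def test_occupancy_is_flag_fraction(self):
        iface = PlantedInterface(
            contacts=(PlantedContact(residue_a=2, residue_b=3, occupancy=0.25),)
        )
        traj, truth = generate_toy_complex(iface, n_frames=20)
        sites = aggregate_sites(traj)
        assert sites[0].occupancy == 5 / 20
        assert sites[0].frames_flagged == truth[0]["frames_on"]

    def test_two_planted_sites_recovered(self):
        iface = PlantedInterface(
            contacts=(
                PlantedContact(residue_a=2, residue_b=2, occupancy=0.9),
                PlantedContact(residue_a=6, residue_b=7, occupancy=0.1),
            )
        )
        traj, truth = generate_toy_complex(iface, n_frames=20, seed=3)
        sites = {(s.residue_a[1], s.residue_b[1]): s for s in aggregate_sites(traj)}
        for rec in truth:
            site = sites[(rec["residue_a"], rec["residue_b"])]
            assert abs(site.occupancy - rec["occupancy"]) <= 1 / 20

    def test_frame_permutation_invariance(self):
        iface = PlantedInterface(
            contacts=(PlantedContact(residue_a=2, residue_b=3, occupancy=0.4),)
        )
        traj, _ = generate_toy_complex(iface, n_frames=10, seed=5)
        perm = np.random.default_rng(0).permutation(10)
        shuffled = Trajectory([traj[i] for i in perm])
        occ = lambda t: {
            (s.residue_a[1], s.residue_b[1]): s.occupancy
            for s in aggregate_sites(t)
        }
        assert occ(traj) == occ(shuffled)

    def test_adjacent_pairs_grouped(self):
        iface = PlantedInterface(
            contacts=(
                PlantedContact(residue_a=2, residue_b=2, occupancy=1.0),
                PlantedContact(residue_a=3, residue_b=2, occupancy=1.0),
                PlantedContact(residue_a=7, residue_b=7, occupancy=1.0),
            )
        )
        traj, _ = generate_toy_complex(iface, n_frames=5)
        sites = aggregate_sites(traj)
        by_pair = {(s.residue_a[1], s.residue_b[1]): s.group_id for s in sites}
        assert by_pair[(2, 2)] == by_pair[(3, 2)]
        assert by_pair[(7, 7)] != by_pair[(2, 2)]

    def test_empty_trajectory_rejected(self):
        with pytest.raises(InvalidParameterError):
            Trajectory([])


def _two_charge_frame(distance, qa=1.0, qb=-1.0):
    return Frame(
        positions=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, distance]]),
        residue_names=np.array(["ALA", "ALA"]),
        residue_numbers=np.array([1, 1]),
        molecule_tags=np.array(["A", "B"]),
        charges=np.array([qa, qb]),
    )


class TestElectrostaticScore:
    def site(self):
        return ContactSite(
            residue_a=("ALA", 1), residue_b=("ALA", 1), frames_flagged=[0],
            occupancy=1.0,
        )

    def test_hand_coulomb_value(self):
        # 332.0636 * (+1) * (-1) / 3.320636 = -100 exactly
        frame = _two_charge_frame(3.320636)
        assert electrostatic_score(self.site(), frame) == pytest.approx(-100.0)

    def test_zero_charges_warn_and_score_zero(self):
        frame = _two_charge_frame(3.0, qa=0.0, qb=0.0)
        with pytest.warns(UserWarning, match="zero"):
            assert electrostatic_score(self.site(), frame) == 0.0

    def test_dielectric_halves_score(self):
        frame = _two_charge_frame(3.320636)
        full = electrostatic_score(self.site(), frame, dielectric=1.0)
        half = electrostatic_score(self.site(), frame, dielectric=2.0)
        assert half == pytest.approx(full / 2)

    def test_beyond_cutoff_ignored(self):
        frame = _two_charge_frame(13.0)
        assert electrostatic_score(self.site(), frame) == 0.0

    def test_scored_via_trajectory_mean(self):
        frame = _two_charge_frame(3.320636)
        traj = Trajectory([frame])
        sites = score_sites([self.site()], traj)
        assert sites[0].electrostatic_score == pytest.approx(-100.0)


class TestClassifyStability:
    def _sites(self, scores):
        out = []
        for i, score in enumerate(scores):
            s = ContactSite(
                residue_a=("ALA", i + 1), residue_b=("ALA", i + 1),
                frames_flagged=[0], occupancy=1.0,
            )
            s.electrostatic_score = score
            out.append(s)
        return out

    def test_ten_percent_rule(self):
        sites = classify_stability(self._sites([-100.0, -50.0, -9.0]))
        assert [s.stable for s in sites] == [True, True, False]

    def test_singleton_is_stable(self):
        (site,) = classify_stability(self._sites([-0.5]))
        assert site.stable

    def test_all_equal_scores_all_stable(self):
        sites = classify_stability(self._sites([-5.0, -5.0, -5.0]))
        assert all(s.stable for s in sites)

    def test_boundary_exactly_ten_percent_is_stable(self):
        sites = classify_stability(self._sites([-100.0, -10.0]))
        assert [s.stable for s in sites] == [True, True]

    def test_empty_list_raises(self):
        with pytest.raises(InvalidParameterError):
            classify_stability([])


class TestContactSiteInvariants:
    def test_occupancy_range_enforced(self):
        with pytest.raises(InvalidParameterError):
            ContactSite(
                residue_a=("ALA", 1), residue_b=("ALA", 1),
                frames_flagged=[0], occupancy=1.5,
            )

    def test_frames_deduplicated_and_sorted(self):
        s = ContactSite(
            residue_a=("ALA", 1), residue_b=("ALA", 1),
            frames_flagged=[3, 1, 3, 2], occupancy=0.5,
        )
        assert s.frames_flagged == [1, 2, 3]
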