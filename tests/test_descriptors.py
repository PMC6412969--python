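import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from fentsar.core import ResidueRoleMap, Snapshot, TrajectoryPool, ValidationError
from fentsar.descriptors import (
    chi_dihedral,
    chi_series,
    circular_mean,
    circular_sem,
    hydration_count,
    hydration_series,
    kruskal_wallis,
    lock_distance_series,
    one_way_anova,
    pair_distance,
    rmsd_series,
    rmsf,
)
from fentsar.synthetic import SyntheticSpec, generate_pool

from conftest import oracle_hydration


def _pool_from_coords(coords, atoms=None, names=None):
    n = coords.shape[1]
    atoms = atoms if atoms is not None else pd.DataFrame(
        {
            "name": names or ["CA"] * n,
            "element": ["C"] * n,
            "residue_number": range(1, n + 1),
            "residue_name": ["ALA"] * n,
            "chain": ["A"] * n,
            "category": ["protein"] * n,
        }
    )
    return TrajectoryPool(
        atoms=atoms,
        coords=coords,
        times=np.arange(coords.shape[0], dtype=float) * 0.01,
        replicas=np.ones(coords.shape[0], dtype=int),
    )


class TestRmsd:
    def test_static_trajectory_is_zero(self):
        coords = np.tile(np.random.default_rng(0).normal(size=(1, 5, 3)), (4, 1, 1))
        pool = _pool_from_coords(coords)
        np.testing.assert_allclose(rmsd_series(pool), 0.0, atol=1e-10)

    def test_rigid_motion_gives_zero_after_superposition(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(6, 3))
        frames = [base]
        for k in range(3):
            rot = Rotation.from_euler("xyz", rng.uniform(-1, 1, 3))
            frames.append(rot.apply(base) + rng.normal(size=3))
        pool = _pool_from_coords(np.stack(frames))
        np.testing.assert_allclose(rmsd_series(pool), 0.0, atol=1e-9)

    def test_two_atom_displacement_matches_hand_formula(self):
        # one atom displaced by d in one frame, no superposition: RMSD = d/sqrt(2)
        d = 1.8
        coords = np.zeros((2, 2, 3))
        coords[:, 1, 0] = 5.0
        coords[1, 1, 0] += d
        pool = _pool_from_coords(coords)
        series = rmsd_series(pool, fit=False, selection=np.array([0, 1]))
        assert series[1] == pytest.approx(d / math.sqrt(2))

    def test_empty_helix_selection_names_the_helix(self, syn):
        rm = ResidueRoleMap(helix_ranges={"H9": (400, 410)})
        with pytest.raises(ValidationError, match="H9"):
            rmsd_series(syn.pool, rm, helix="H9")


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        coords = np.tile(np.random.default_rng(0).normal(size=(1, 4, 3)), (3, 1, 1))
        per_atom, mean = rmsf(_pool_from_coords(coords))
        np.testing.assert_allclose(per_atom, 0.0, atol=1e-10)

    def test_two_point_alternation_equals_amplitude(self):
        # an atom alternating +a/-a about its mean has RMSF = a (others anchor the fit)
        a = 0.7
        base = np.array(
            [[10.0, 0, 0], [-10.0, 0, 0], [0, 10.0, 0], [0, -10.0, 0], [0, 0, 0]]
        )
        coords = np.tile(base, (4, 1, 1))
        coords[::2, 4, 2] = a
        coords[1::2, 4, 2] = -a
        per_atom, _ = rmsf(_pool_from_coords(coords), fit=False,
                           selection=np.arange(5))
        assert per_atom[4] == pytest.approx(a)
        np.testing.assert_allclose(per_atom[:4], 0.0, atol=1e-12)

    def test_uniform_translation_removed_by_superposition(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(5, 3))
        wobble = rng.normal(0, 0.1, size=(6, 5, 3))
        coords = base + wobble
        shifted = coords + rng.normal(size=(6, 1, 3)) * 5
        _, m1 = rmsf(_pool_from_coords(coords))
        _, m2 = rmsf(_pool_from_coords(shifted))
        assert m2 == pytest.approx(m1, abs=1e-9)

    def test_single_frame_is_an_error(self):
        with pytest.raises(ValidationError, match="RMSF"):
            rmsf(_pool_from_coords(np.zeros((1, 3, 3))))


def _chi_snapshot(d_pos):
    """ASP-like residue with N, CA, CB, CG at given CG position."""
    atoms = pd.DataFrame(
        {
            "name": ["N", "CA", "CB", "CG"],
            "element": ["N", "C", "C", "C"],
            "residue_number": [147] * 4,
            "residue_name": ["ASP"] * 4,
            "chain": ["A"] * 4,
            "category": ["protein"] * 4,
        }
    )
    positions = np.array(
        [[0.0, 1.5, 0.0], [0.0, 0.0, 0.0], [1.5, 0.0, 0.0], list(d_pos)]
    )
    return Snapshot(atoms=atoms, positions=positions, time=0.0, replica_id=1)


class TestChiDihedral:
    ROLE_MAP = ResidueRoleMap()

    def test_cis_is_zero(self):
        snap = _chi_snapshot([2.2, 1.3, 0.0])  # same side as N
        assert chi_dihedral(snap, self.ROLE_MAP, "D147", "X1") == pytest.approx(
            0.0, abs=1e-9
        )

    def test_trans_is_180(self):
        snap = _chi_snapshot([2.2, -1.3, 0.0])
        assert chi_dihedral(snap, self.ROLE_MAP, "D147", "X1") == pytest.approx(180.0)

    def test_gauche_minus_matches_atan2_oracle(self):
        # rotate the trans atom by -120 deg about the CA->CB axis (+x)
        th = math.radians(-120)
        y, z = -1.3, 0.0
        snap = _chi_snapshot(
            [2.2, y * math.cos(th) - z * math.sin(th), y * math.sin(th) + z * math.cos(th)]
        )
        got = chi_dihedral(snap, self.ROLE_MAP, "D147", "X1")
        # independent oracle from cross/dot products
        p = snap.positions
        b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        oracle = math.degrees(
            math.atan2(
                np.dot(np.cross(n1, b2 / np.linalg.norm(b2)), n2), np.dot(n1, n2)
            )
        )
        assert got == pytest.approx(oracle, abs=1e-9)
        assert got == pytest.approx(-60.0, abs=1e-6)

    def test_missing_atom_names_atom_and_residue(self):
        snap = _chi_snapshot([2.2, 1.3, 0.0])
        snap.atoms = snap.atoms[snap.atoms["name"] != "CG"].reset_index(drop=True)
        snap.positions = snap.positions[:3]
        with pytest.raises(ValidationError, match="CG.*147|147.*CG"):
            chi_dihedral(snap, self.ROLE_MAP, "D147", "X1")


class TestCircularMean:
    @pytest.mark.parametrize(
        "angles,expected",
        [([30, 30], 30.0), ([179, -179], 180.0), ([0, 90], 45.0)],
    )
    def test_known_values(self, angles, expected):
        assert circular_mean(angles) == pytest.approx(expected, abs=1e-9)

    def test_degenerate_direction_reported_missing(self):
        assert math.isnan(circular_mean([0.0, 90.0, 180.0, 270.0]))

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValidationError):
            circular_mean([])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=-180, max_value=180), min_size=1, max_size=20),
        st.integers(min_value=-2, max_value=2),
    )
    def test_invariant_under_adding_full_turns(self, angles, k):
        base = circular_mean(angles)
        shifted = list(angles)
        shifted[0] += 360.0 * k
        other = circular_mean(shifted)
        if math.isnan(base):
            assert math.isnan(other)
        else:
            assert abs((base - other + 180) % 360 - 180) < 1e-7

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=10.0, max_value=20.0), min_size=1, max_size=30)
    )
    def test_approaches_arithmetic_mean_on_narrow_arc(self, angles):
        # the two means agree to O(width^2) on a narrow arc, exactly so for
        # identical angles
        assert circular_mean(angles) == pytest.approx(
            float(np.mean(angles)), abs=0.02
        )
        assert circular_mean([angles[0]] * 3) == pytest.approx(
            angles[0], abs=1e-9
        )


class TestDistancesAndHydration:
    def test_pair_distance_345(self):
        coords = np.array([[[0.0, 0, 0], [3.0, 4.0, 0]]])
        pool = _pool_from_coords(coords)
        assert pair_distance(pool.snapshot(0), 0, 1) == pytest.approx(5.0)

    def test_coincident_atoms_zero(self):
        pool = _pool_from_coords(np.zeros((1, 2, 3)))
        assert pair_distance(pool.snapshot(0), 0, 1) == 0.0

    def _water_system(self, o_positions, res_pos=(0.0, 0.0, 0.0)):
        rows = [
            {"name": "CB", "element": "C", "residue_number": 147,
             "residue_name": "ASP", "chain": "A", "category": "protein"}
        ]
        coords = [list(res_pos)]
        for k, o in enumerate(o_positions):
            for name, elem, off in (
                ("OW", "O", (0, 0, 0)), ("HW1", "H", (0.96, 0, 0)),
                ("HW2", "H", (-0.24, 0.93, 0)),
            ):
                rows.append(
                    {"name": name, "element": elem, "residue_number": 1000 + k,
                     "residue_name": "HOH", "chain": "W", "category": "water"}
                )
                coords.append([o[0] + off[0], o[1] + off[1], o[2] + off[2]])
        atoms = pd.DataFrame(rows)
        pool = TrajectoryPool(
            atoms=atoms, coords=np.array(coords)[None], times=[0.0], replicas=[1]
        )
        return pool.snapshot(0)

    def test_counts_across_the_cutoff(self):
        snap = self._water_system([(4.9, 0, 0), (5.1 + 1.0, 0, 0)])
        # second molecule: O at 6.1 but its HW2 is still > 5.0 away
        rm = ResidueRoleMap()
        assert hydration_count(snap, rm, "D147") == 1

    def test_molecule_counted_once_when_only_hydrogen_inside(self):
        # O at 5.5, but HW1 at 5.5-0.96 < 5.0: still counts, exactly once
        snap = self._water_system([(-5.5, 0, 0)])
        rm = ResidueRoleMap()
        assert hydration_count(snap, rm, "D147") == 1
        assert oracle_hydration(snap, rm, "D147") == 1

    def test_no_waters_gives_zero(self):
        snap = self._water_system([])
        assert hydration_count(snap, ResidueRoleMap(), "D147") == 0


class TestHydrationOracle:
    def test_matches_brute_force_on_synthetic_frames(self, syn):
        pool, rm = syn.pool, syn.role_map
        rng = np.random.default_rng(5)
        frames = rng.choice(pool.n_frames, size=25, replace=False)
        for role in ("D114", "Y336"):
            series = hydration_series(pool, rm, role)
            for i in frames:
                assert series[i] == oracle_hydration(pool.snapshot(i), rm, role)


class TestGroupTests:
    def test_identical_groups_fail_to_reject(self):
        g = [[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]]
        assert not kruskal_wallis(g).reject
        assert not one_way_anova(g).reject
        assert kruskal_wallis(g).pvalue == 1.0

    def test_separated_groups_reject(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)
        assert kruskal_wallis([a, b]).reject
        assert one_way_anova([a, b]).reject

    def test_tiny_group_is_an_error(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1.0], [1.0, 2.0]])


class TestParameterRecovery:
    """Generator ground truth is recovered from the data alone."""

    def test_circular_means_within_three_sem(self, syn):
        for key, (mu, sd) in syn.truth["dihedral_laws"].items():
            role, which = key.rsplit("_", 1)
            series = chi_series(syn.pool, syn.role_map, role, which)
            cm = circular_mean(series)
            sem = circular_sem(series)
            err = abs((cm - mu + 180) % 360 - 180)
            assert err <= 3 * sem + 1e-9, (key, cm, mu, sem)

    def test_hydration_means_within_three_sigma(self, syn):
        n = syn.pool.n_frames
        for role, lam in syn.truth["hydration_rates"].items():
            mean = hydration_series(syn.pool, syn.role_map, role).mean()
            assert abs(mean - lam) <= 3 * math.sqrt(lam / n)

    def test_lock_distance_mean_matches_law(self, syn):
        series = lock_distance_series(syn.pool, syn.role_map)
        sem = syn.truth["lock_sd"] / math.sqrt(syn.pool.n_frames)
        assert abs(series.mean() - syn.truth["lock_mean"]) <= 4 * sem

    def test_degenerate_law_collapses_to_mean(self, small_role_map):
        laws = {("W293", "X2"): (-100.0, 0.0)}
        sp = generate_pool(
            SyntheticSpec(seed=3, per_ns=2, dihedral_laws=laws,
                          role_map=small_role_map)
        )
        series = chi_series(sp.pool, sp.role_map, "W293", "X2")
        np.testing.assert_allclose(series, -100.0, atol=1e-6)
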