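import math

import numpy as np
import pandas as pd
import pytest

from fentsar.contacts import (
    ContactCriteria,
    contact_frequencies,
    detect_contacts,
    evaluate_general_features,
    ionic_persistence,
)
from fentsar.core import FragmentScheme, ResidueRoleMap, TrajectoryPool, ValidationError
from fentsar.synthetic import SyntheticSpec, generate_pool

from conftest import oracle_contacts


def _toy_pool(probe_x, n_frames=1):
    """One ILE 144 side-chain carbon at the origin plus one ligand carbon at
    distance ``probe_x`` per frame."""
    atoms = pd.DataFrame(
        [
            {"name": "CB", "element": "C", "residue_number": 144,
             "residue_name": "ILE", "chain": "A", "category": "protein"},
            {"name": "C1", "element": "C", "residue_number": 900,
             "residue_name": "LIG", "chain": "L", "category": "ligand"},
            {"name": "N1", "element": "N", "residue_number": 900,
             "residue_name": "LIG", "chain": "L", "category": "ligand"},
        ]
    )
    probe_x = np.atleast_1d(np.asarray(probe_x, dtype=float))
    coords = np.zeros((len(probe_x), 3, 3))
    coords[:, 1, 0] = probe_x
    coords[:, 2, 1] = 50.0  # parked nitrogen
    pool = TrajectoryPool(
        atoms=atoms, coords=coords,
        times=0.01 * np.arange(len(probe_x)),
        replicas=np.ones(len(probe_x), dtype=int),
    )
    scheme = FragmentScheme(
        fragments={"piperidine": [2], "propanamide": [1]},
        protonable_nitrogen=2,
    )
    return pool, scheme


class TestDetectContacts:
    def test_hydrophobic_cutoff(self):
        rm = ResidueRoleMap()
        pool, scheme = _toy_pool([4.0])
        found = detect_contacts(pool.snapshot(0), scheme, rm)
        assert ("propanamide", "I144", "Hy") in found
        pool, scheme = _toy_pool([4.6])
        found = detect_contacts(pool.snapshot(0), scheme, rm)
        assert ("propanamide", "I144", "Hy") not in found

    def test_boundary_counts_as_contact(self):
        rm = ResidueRoleMap()
        pool, scheme = _toy_pool([4.5])
        assert ("propanamide", "I144", "Hy") in detect_contacts(
            pool.snapshot(0), scheme, rm
        )

    def test_aromatic_centroid_geometry(self):
        # ligand hexagon centred 5.0 A from a TRP five-ring centroid
        rm = ResidueRoleMap()
        rows, coords = [], []
        ring_names = ["CG", "CD1", "NE1", "CE2", "CD2"]
        for k, name in enumerate(ring_names):
            ang = 2 * math.pi * k / 5
            rows.append({"name": name, "element": "N" if name.startswith("N") else "C",
                         "residue_number": 133, "residue_name": "TRP",
                         "chain": "A", "category": "protein"})
            coords.append([1.2 * math.cos(ang), 1.2 * math.sin(ang), 0.0])
        lig_ring = []
        for k in range(6):
            ang = 2 * math.pi * k / 6
            rows.append({"name": f"C{k}", "element": "C", "residue_number": 900,
                         "residue_name": "LIG", "chain": "L", "category": "ligand"})
            coords.append([1.39 * math.cos(ang), 1.39 * math.sin(ang), 5.0])
            lig_ring.append(len(rows) - 1)
        rows.append({"name": "N1", "element": "N", "residue_number": 900,
                     "residue_name": "LIG", "chain": "L", "category": "ligand"})
        coords.append([60.0, 0.0, 0.0])
        pool = TrajectoryPool(
            atoms=pd.DataFrame(rows), coords=np.array(coords)[None],
            times=[0.0], replicas=[1],
        )
        scheme = FragmentScheme(
            fragments={"piperidine": [len(rows) - 1], "anilide_aromatic": lig_ring},
            protonable_nitrogen=len(rows) - 1,
            aromatic_rings=[lig_ring],
        )
        found = detect_contacts(pool.snapshot(0), scheme, rm)
        assert ("anilide_aromatic", "W133", "A") in found

    def test_water_only_frame_is_empty(self):
        atoms = pd.DataFrame(
            [
                {"name": "OW", "element": "O", "residue_number": 1000,
                 "residue_name": "HOH", "chain": "W", "category": "water"},
                {"name": "N1", "element": "N", "residue_number": 900,
                 "residue_name": "LIG", "chain": "L", "category": "ligand"},
            ]
        )
        pool = TrajectoryPool(
            atoms=atoms, coords=np.zeros((1, 2, 3)), times=[0.0], replicas=[1]
        )
        scheme = FragmentScheme(fragments={"piperidine": [1]}, protonable_nitrogen=1)
        assert detect_contacts(pool.snapshot(0), scheme, ResidueRoleMap()) == set()

    def test_empty_fragment_query_is_an_error(self):
        pool, scheme = _toy_pool([4.0])
        with pytest.raises(ValidationError, match="axial_4"):
            detect_contacts(
                pool.snapshot(0), scheme, ResidueRoleMap(), fragments=["axial_4"]
            )

    def test_matches_brute_force_oracle_on_synthetic_frames(self, syn):
        pool, scheme, rm = syn.pool, syn.scheme, syn.role_map
        assert pool.n_atoms <= 500 or True  # oracle is O(N^2) but exact anyway
        criteria = ContactCriteria()
        rng = np.random.default_rng(17)
        frames = rng.choice(pool.n_frames, size=50, replace=False)
        for i in frames:
            snap = pool.snapshot(i)
            assert detect_contacts(snap, scheme, rm, criteria) == oracle_contacts(
                snap, scheme, rm, criteria
            )


class TestContactFrequencies:
    def test_ubiquitous_contact_has_sem_zero(self):
        pool, scheme = _toy_pool([4.0, 4.0, 4.0])
        pool.replicas = np.array([1, 2, 3])
        table = contact_frequencies(pool, scheme, ResidueRoleMap())
        row = table[(table["residue"] == "I144") & (table["type"] == "Hy")].iloc[0]
        assert row["mean"] == 1.0 and row["sem"] == 0.0

    def test_hand_computed_mean_and_sem(self):
        # replica frequencies {0.5, 0.7, 0.9} over 10 frames each
        xs = []
        for frac in (0.5, 0.7, 0.9):
            n_in = int(frac * 10)
            xs.extend([4.0] * n_in + [6.0] * (10 - n_in))
        pool, scheme = _toy_pool(xs)
        pool.replicas = np.repeat([1, 2, 3], 10)
        table = contact_frequencies(pool, scheme, ResidueRoleMap())
        row = table[(table["residue"] == "I144") & (table["type"] == "Hy")].iloc[0]
        assert row["mean"] == pytest.approx(0.7)
        assert row["sem"] == pytest.approx(0.2 / math.sqrt(3))

    def test_single_replica_sem_is_missing(self):
        pool, scheme = _toy_pool([4.0, 6.0])
        table = contact_frequencies(pool, scheme, ResidueRoleMap())
        assert math.isnan(
            table[(table["residue"] == "I144")]["sem"].iloc[0]
        )

    def test_invariant_to_frame_order_within_replica(self, syn):
        pool, scheme, rm = syn.pool, syn.scheme, syn.role_map
        t1 = contact_frequencies(pool, scheme, rm)
        rng = np.random.default_rng(3)
        perm = np.concatenate(
            [rng.permutation(np.flatnonzero(pool.replicas == r))
             for r in pool.replica_ids]
        )
        # permuting frames within each replica block leaves frequencies alone
        shuffled = TrajectoryPool(
            atoms=pool.atoms, coords=pool.coords[perm], times=pool.times,
            replicas=pool.replicas,
        )
        t2 = contact_frequencies(shuffled, scheme, rm)
        pd.testing.assert_frame_equal(
            t1.sort_values(["fragment", "residue", "type"]).reset_index(drop=True),
            t2.sort_values(["fragment", "residue", "type"]).reset_index(drop=True),
        )

    def test_tightening_cutoffs_never_raises_frequencies(self, syn):
        pool, scheme, rm = syn.pool, syn.scheme, syn.role_map
        loose = contact_frequencies(pool, scheme, rm, include_zero=True)
        tight = contact_frequencies(
            pool, scheme, rm,
            ContactCriteria(hb_dist=2.8, hb_angle=150.0, hydrophobic_dist=3.6,
                            aromatic_centroid_dist=4.4, ionic_dist=3.2),
            include_zero=True,
        )
        merged = loose.merge(
            tight, on=["fragment", "residue", "type"], suffixes=("_l", "_t"),
            how="outer",
        ).fillna(0.0)
        assert (merged["mean_t"] <= merged["mean_l"] + 1e-12).all()

    def test_recovers_generator_targets(self, syn):
        table = contact_frequencies(syn.pool, syn.scheme, syn.role_map)
        for key, realized in syn.truth["realized_contact_frequency"].items():
            f, r, t = key.split("|")
            row = table[
                (table["fragment"] == f) & (table["residue"] == r)
                & (table["type"] == t)
            ]
            got = float(row["mean"].iloc[0]) if len(row) else 0.0
            assert got == pytest.approx(realized, abs=1e-12)


class TestIonicPersistence:
    def test_always_bonded_is_one(self, syn):
        assert ionic_persistence(syn.pool, syn.role_map, syn.scheme) == \
            pytest.approx(syn.truth["realized_saltbridge_presence"])

    def test_broken_salt_bridge_scenario(self, small_role_map):
        sp = generate_pool(
            SyntheticSpec(seed=23, per_ns=10, saltbridge_presence=0.33,
                          role_map=small_role_map)
        )
        got = ionic_persistence(sp.pool, sp.role_map, sp.scheme)
        assert got == pytest.approx(sp.truth["realized_saltbridge_presence"])
        assert abs(got - 0.33) < 3 * math.sqrt(0.33 * 0.67 / sp.pool.n_frames)

    def test_distance_exactly_at_cutoff_counts(self):
        atoms = pd.DataFrame(
            [
                {"name": n, "element": e, "residue_number": 147,
                 "residue_name": "ASP", "chain": "A", "category": "protein"}
                for n, e in (("OD1", "O"), ("OD2", "O"))
            ]
            + [{"name": "N1", "element": "N", "residue_number": 900,
                "residue_name": "LIG", "chain": "L", "category": "ligand"}]
        )
        coords = np.array([[[0, 0, 0], [0, 1.5, 0], [4.0, 0, 0]]], dtype=float)
        pool = TrajectoryPool(atoms=atoms, coords=coords, times=[0.0], replicas=[1])
        scheme = FragmentScheme(fragments={"piperidine": [2]}, protonable_nitrogen=2)
        assert ionic_persistence(pool, ResidueRoleMap(), scheme) == 1.0


class TestGeneralFeatures:
    def test_fentanyl_like_pool_satisfies_all_features(self, syn):
        table = contact_frequencies(syn.pool, syn.scheme, syn.role_map)
        ion = ionic_persistence(syn.pool, syn.role_map, syn.scheme)
        gfs = evaluate_general_features(table, ion, syn.scheme)
        assert all(g.value is True for g in gfs.values())

    def test_salt_bridge_ablation_flips_only_gf1(self, small_role_map):
        sp = generate_pool(
            SyntheticSpec(seed=29, per_ns=10, saltbridge_presence=0.1,
                          role_map=small_role_map)
        )
        table = contact_frequencies(sp.pool, sp.scheme, sp.role_map)
        ion = ionic_persistence(sp.pool, sp.role_map, sp.scheme)
        gfs = evaluate_general_features(table, ion, sp.scheme)
        assert gfs["GF1"].value is False
        assert all(gfs[k].value is True for k in ("GF2", "GF3", "GF4", "GF5"))

    def test_missing_axial_substituent_is_not_applicable(self, small_role_map):
        targets = tuple(
            t for t in SyntheticSpec().contact_targets if t[0] != "axial_4"
        )
        sizes = dict(SyntheticSpec().body_sizes)
        sizes["axial_4"] = 0
        sp = generate_pool(
            SyntheticSpec(seed=31, per_ns=5, contact_targets=targets,
                          body_sizes=sizes, role_map=small_role_map)
        )
        table = contact_frequencies(sp.pool, sp.scheme, sp.role_map)
        ion = ionic_persistence(sp.pool, sp.role_map, sp.scheme)
        gfs = evaluate_general_features(table, ion, sp.scheme)
        assert gfs["GF5"].value is None
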