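import numpy as np
import pytest

from fentsar.core import ResidueRoleMap
from fentsar.synthetic import SyntheticSpec, generate_pool


@pytest.fixture(scope="session")
def small_role_map() -> ResidueRoleMap:
    """Full role set but only two short helices, to keep pools small."""
    return ResidueRoleMap(helix_ranges={"H1": (72, 75), "H2": (104, 107)})


@pytest.fixture(scope="session")
def syn(small_role_map):
    """A compact synthetic pool: 3 replicas x 100 frames, default laws."""
    spec = SyntheticSpec(seed=11, per_ns=10, role_map=small_role_map)
    return generate_pool(spec)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (plain loops, own constant tables)
# ---------------------------------------------------------------------------

_ORACLE_APOLAR = {
    "ALA": {"CB"}, "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"}, "ILE": {"CB", "CG1", "CG2", "CD1"},
    "MET": {"CB", "CG", "SD", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "PRO": {"CB", "CG"}, "THR": {"CG2"}, "CYS": {"CB", "SG"},
    "LYS": {"CB", "CG", "CD"}, "ARG": {"CB", "CG"}, "GLN": {"CB", "CG"},
    "GLU": {"CB", "CG"}, "ASP": {"CB"}, "ASN": {"CB"}, "HIS": {"CB"},
}
_ORACLE_RING = {
    "TRP": ["CG", "CD1", "NE1", "CE2", "CD2"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
}
_ORACLE_CARBOX = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}


def _dist(p, q):
    return float(np.linalg.norm(np.asarray(p) - np.asarray(q)))


def oracle_hydration(snapshot, role_map, role, cutoff=5.0):
    """O(N^2) hydration count: loop every water atom vs every residue atom."""
    atoms = snapshot.atoms
    resnum = role_map.residue_number(role)
    res_pos = [
        snapshot.positions[i]
        for i in range(len(atoms))
        if atoms["residue_number"].iloc[i] == resnum
        and atoms["category"].iloc[i] == "protein"
    ]
    molecules = set()
    for i in range(len(atoms)):
        if atoms["category"].iloc[i] != "water":
            continue
        key = (atoms["chain"].iloc[i], int(atoms["residue_number"].iloc[i]))
        if key in molecules:
            continue
        for rp in res_pos:
            if _dist(snapshot.positions[i], rp) <= cutoff:
                molecules.add(key)
                break
    return len(molecules)


def oracle_contacts(snapshot, scheme, role_map, criteria):
    """Brute-force contact typing by definition, independent of the engine."""
    atoms = snapshot.atoms
    pos = snapshot.positions
    elem = atoms["element"]
    names = atoms["name"]

    # ligand apolar: C/S not bonded to N/O (all C/S if no bonds declared)
    lig_atoms = set(int(i) for i in scheme.all_atoms())
    adj = {}
    for a, b2 in scheme.bonds or []:
        adj.setdefault(a, set()).add(b2)
        adj.setdefault(b2, set()).add(a)
    lig_apolar = set()
    for i in lig_atoms:
        if elem.iloc[i] in ("C", "S"):
            if scheme.bonds is None or not any(
                elem.iloc[j] in ("N", "O") for j in adj.get(i, ())
            ):
                lig_apolar.add(i)
    lig_polar = [i for i in lig_atoms if elem.iloc[i] in ("N", "O")]
    h_atoms = [i for i in range(len(atoms)) if elem.iloc[i] == "H"]

    def attached_h(i):
        return [h for h in h_atoms if _dist(pos[h], pos[i]) <= 1.25]

    found = set()
    for role, resnum in role_map.roles.items():
        res_name = role_map.residue_name(role)
        res_idx = [
            i for i in range(len(atoms))
            if atoms["residue_number"].iloc[i] == resnum
            and atoms["category"].iloc[i] == "protein"
        ]
        if not res_idx:
            continue
        res_apolar = [
            i for i in res_idx if names.iloc[i] in _ORACLE_APOLAR.get(res_name, ())
        ]
        res_polar = [i for i in res_idx if elem.iloc[i] in ("N", "O")]
        ring_names = _ORACLE_RING.get(res_name)
        res_ring = None
        if ring_names:
            hits = [i for i in res_idx if names.iloc[i] in ring_names]
            if len(hits) == len(ring_names):
                res_ring = hits
        carbox = [
            i for i in res_idx if names.iloc[i] in _ORACLE_CARBOX.get(res_name, ())
        ]
        for label, frag in scheme.fragments.items():
            frag = [int(i) for i in frag]
            # Hy
            for i in frag:
                if i not in lig_apolar:
                    continue
                if any(
                    _dist(pos[i], pos[j]) <= criteria.hydrophobic_dist
                    for j in res_apolar
                ):
                    found.add((label, role, "Hy"))
                    break
            # Hb
            done = False
            for i in frag:
                if i not in lig_polar or done:
                    continue
                for j in res_polar:
                    if _dist(pos[i], pos[j]) > criteria.hb_dist:
                        continue
                    hs = [(h, i, j) for h in attached_h(i)]
                    hs += [(h, j, i) for h in attached_h(j)]
                    if not hs:
                        found.add((label, role, "Hb"))
                        done = True
                        break
                    for h, dnr, acc in hs:
                        v1 = pos[dnr] - pos[h]
                        v2 = pos[acc] - pos[h]
                        cosang = np.dot(v1, v2) / (
                            np.linalg.norm(v1) * np.linalg.norm(v2)
                        )
                        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                        if ang >= criteria.hb_angle:
                            found.add((label, role, "Hb"))
                            done = True
                            break
                    if done:
                        break
            # A
            if res_ring is not None:
                for ring in scheme.aromatic_rings:
                    if not set(ring) <= set(frag):
                        continue
                    ca = np.mean([pos[i] for i in ring], axis=0)
                    cb = np.mean([pos[i] for i in res_ring], axis=0)
                    if _dist(ca, cb) <= criteria.aromatic_centroid_dist:
                        found.add((label, role, "A"))
            # Ionic
            if carbox and scheme.protonable_nitrogen in frag:
                if any(
                    _dist(pos[scheme.protonable_nitrogen], pos[j])
                    <= criteria.ionic_dist
                    for j in carbox
                ):
                    found.add((label, role, "Ionic"))
    return found
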