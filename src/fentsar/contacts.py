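"""Typed ligand-fragment / receptor-residue contact fingerprints.

A contact is a triple ``(fragment, residue role, type)`` evaluated per frame;
it is recorded once per frame no matter how many atom pairs satisfy the
geometry.  Types follow interaction-fingerprint practice:

``Hy``
    hydrophobic: an apolar heavy-atom pair (carbon/sulfur not bonded to N/O)
    within ``hydrophobic_dist``.
``Hb``
    hydrogen bond: donor-acceptor heavy atoms (N/O) within ``hb_dist``; when
    hydrogens are present on the donor the D-H...A angle must exceed
    ``hb_angle``, otherwise the heavy-atom distance alone decides.
``A``
    aromatic: ring-centroid distance within ``aromatic_centroid_dist``
    (no plane-angle term).
``Ionic``
    the ligand's protonable nitrogen within ``ionic_dist`` of a carboxylate
    oxygen (Asp/Glu).

The cutoffs are this module's own defaults, configurable via
:class:`ContactCriteria`; boundary values count as contacts (``<=``).
Frequencies are aggregated per replica (fraction of that replica's frames)
and reported as mean +/- SEM across replicas, SEM being sd/sqrt(n_replicas).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    FRAGMENT_LABELS,
    FragmentScheme,
    ResidueRoleMap,
    Snapshot,
    TrajectoryPool,
    ValidationError,
)

__all__ = [
    "ContactCriteria",
    "GeneralFeature",
    "contact_frequencies",
    "detect_contacts",
    "evaluate_general_features",
    "ionic_persistence",
]


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric cutoffs for contact typing (Angstrom / degrees)."""

    hb_dist: float = 3.5
    hb_angle: float = 120.0
    hydrophobic_dist: float = 4.5
    aromatic_centroid_dist: float = 5.5
    ionic_dist: float = 4.0

    def __post_init__(self) -> None:
        for name in ("hb_dist", "hb_angle", "hydrophobic_dist",
                     "aromatic_centroid_dist", "ionic_dist"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"criterion {name} must be positive")


#: Side-chain carbons/sulfurs not bonded to N/O, per residue type.
APOLAR_SIDECHAIN = {
    "ALA": ("CB",),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2"),
    "PRO": ("CB", "CG"),
    "THR": ("CG2",),
    "CYS": ("CB", "SG"),
    "LYS": ("CB", "CG", "CD"),
    "ARG": ("CB", "CG"),
    "GLN": ("CB", "CG"),
    "GLU": ("CB", "CG"),
    "ASP": ("CB",),
    "ASN": ("CB",),
    "HIS": ("CB",),
}

AROMATIC_RING_ATOMS = {
    "TRP": ("CG", "CD1", "NE1", "CE2", "CD2"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

CARBOXYLATE_OXYGENS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


def _ligand_apolar_atoms(atoms: pd.DataFrame, scheme: FragmentScheme) -> set[int]:
    """Ligand C/S atoms not bonded to N/O; without declared bonds every
    ligand C/S counts (documented fallback)."""
    elements = atoms["element"]
    cs = {
        int(i)
        for i in scheme.all_atoms()
        if elements.iloc[int(i)] in ("C", "S")
    }
    if scheme.bonds is None:
        return cs
    adj = scheme.neighbours()
    out = set()
    for i in cs:
        if not any(elements.iloc[j] in ("N", "O") for j in adj.get(i, ())):
            out.add(i)
    return out


def _attached_hydrogens(
    atoms: pd.DataFrame, positions: np.ndarray, heavy: Sequence[int]
) -> dict[int, np.ndarray]:
    """Hydrogens within covalent range (1.25 A) of each heavy atom, resolved
    on the reference frame; attachment is treated as constant."""
    h_idx = np.flatnonzero(atoms["element"].to_numpy() == "H")
    out: dict[int, np.ndarray] = {}
    if h_idx.size == 0:
        return {int(i): np.empty(0, dtype=int) for i in heavy}
    hp = positions[h_idx]
    for i in heavy:
        d = np.linalg.norm(hp - positions[int(i)], axis=1)
        out[int(i)] = h_idx[d <= 1.25]
    return out


class _ContactEngine:
    """Precomputed atom-index tasks for one (atom table, scheme, role map);
    evaluates all candidate contacts over a coordinate stack at once."""

    def __init__(
        self,
        atoms: pd.DataFrame,
        ref_positions: np.ndarray,
        scheme: FragmentScheme,
        role_map: ResidueRoleMap,
        criteria: ContactCriteria,
    ) -> None:
        self.criteria = criteria
        self.tasks: list[tuple[str, tuple[str, str, str], dict]] = []
        lig_apolar = _ligand_apolar_atoms(atoms, scheme)
        elements = atoms["element"].to_numpy()
        names = atoms["name"].to_numpy()
        polar_heavy = np.isin(elements, ["N", "O"])
        lig_polar_all = [
            int(i) for i in scheme.all_atoms() if polar_heavy[int(i)]
        ]
        hydro = _attached_hydrogens(
            atoms, ref_positions, lig_polar_all
        )

        ring_by_fragment: dict[str, list[np.ndarray]] = {}
        for ring in scheme.aromatic_rings:
            for label in FRAGMENT_LABELS:
                if set(ring) <= set(scheme.fragments.get(label, [])):
                    ring_by_fragment.setdefault(label, []).append(
                        np.asarray(ring, dtype=int)
                    )
                    break

        for role in role_map.roles:
            resnum = role_map.residue_number(role)
            res_name = role_map.residue_name(role)
            res_mask = (
                (atoms["residue_number"].to_numpy() == resnum)
                & (atoms["category"].to_numpy() == "protein")
            )
            res_idx = np.flatnonzero(res_mask)
            if res_idx.size == 0:
                continue
            res_names = names[res_idx]
            res_apolar = res_idx[
                np.isin(res_names, APOLAR_SIDECHAIN.get(res_name, ()))
            ]
            res_polar = res_idx[polar_heavy[res_idx]]
            res_hydro = _attached_hydrogens(atoms, ref_positions, res_polar)
            ring_names = AROMATIC_RING_ATOMS.get(res_name)
            res_ring = None
            if ring_names is not None:
                hit = res_idx[np.isin(res_names, ring_names)]
                if hit.size == len(ring_names):
                    res_ring = hit
            carbox = res_idx[
                np.isin(res_names, CARBOXYLATE_OXYGENS.get(res_name, ()))
            ]

            for label in FRAGMENT_LABELS:
                frag = np.asarray(scheme.fragments.get(label, []), dtype=int)
                if frag.size == 0:
                    continue
                frag_apolar = np.asarray(
                    sorted(set(map(int, frag)) & lig_apolar), dtype=int
                )
                if frag_apolar.size and res_apolar.size:
                    self.tasks.append(
                        ("hy", (label, role, "Hy"),
                         {"a": frag_apolar, "b": res_apolar})
                    )
                frag_polar = np.asarray(
                    [i for i in frag if polar_heavy[int(i)]], dtype=int
                )
                if frag_polar.size and res_polar.size:
                    self.tasks.append(
                        ("hb", (label, role, "Hb"),
                         {"a": frag_polar, "b": res_polar,
                          "ha": hydro, "hb": res_hydro})
                    )
                if res_ring is not None:
                    for ring in ring_by_fragment.get(label, []):
                        self.tasks.append(
                            ("ar", (label, role, "A"),
                             {"a": ring, "b": res_ring})
                        )
                if carbox.size and int(scheme.protonable_nitrogen) in set(
                    map(int, frag)
                ):
                    self.tasks.append(
                        ("ionic", (label, role, "Ionic"),
                         {"a": np.asarray([scheme.protonable_nitrogen]),
                          "b": carbox})
                    )

    # -- per-type evaluators (coords: (frames, atoms, 3)) ----------------
    @staticmethod
    def _min_dist_within(coords, a, b, cutoff) -> np.ndarray:
        pa = coords[:, a, None, :]
        pb = coords[:, None, b, :]
        d2 = ((pa - pb) ** 2).sum(-1)
        return d2.reshape(coords.shape[0], -1).min(axis=1) <= cutoff * cutoff

    def _eval_hb(self, coords, a, b, ha, hb) -> np.ndarray:
        c = self.criteria
        n_frames = coords.shape[0]
        result = np.zeros(n_frames, dtype=bool)
        cos_max = math.cos(math.radians(c.hb_angle))
        for x in a:
            for y in b:
                d = np.linalg.norm(coords[:, x] - coords[:, y], axis=1)
                d_ok = d <= c.hb_dist
                if not d_ok.any():
                    continue
                h_list = [(int(h), int(x), int(y)) for h in ha.get(int(x), ())]
                h_list += [(int(h), int(y), int(x)) for h in hb.get(int(y), ())]
                if not h_list:
                    result |= d_ok
                    continue
                angle_ok = np.zeros(n_frames, dtype=bool)
                for h, donor, acceptor in h_list:
                    v1 = coords[:, donor] - coords[:, h]
                    v2 = coords[:, acceptor] - coords[:, h]
                    cosang = np.sum(v1 * v2, axis=1) / (
                        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
                    )
                    # D-H...A angle >= hb_angle  <=>  cos(angle) <= cos(hb_angle)
                    angle_ok |= cosang <= cos_max + 1e-12
                result |= d_ok & angle_ok
        return result

    def evaluate(self, coords: np.ndarray) -> dict[tuple[str, str, str], np.ndarray]:
        c = self.criteria
        out: dict[tuple[str, str, str], np.ndarray] = {}
        for kind, key, idx in self.tasks:
            if kind == "hy":
                hit = self._min_dist_within(coords, idx["a"], idx["b"], c.hydrophobic_dist)
            elif kind == "hb":
                hit = self._eval_hb(coords, idx["a"], idx["b"], idx["ha"], idx["hb"])
            elif kind == "ar":
                ca = coords[:, idx["a"], :].mean(axis=1)
                cb = coords[:, idx["b"], :].mean(axis=1)
                hit = np.linalg.norm(ca - cb, axis=1) <= c.aromatic_centroid_dist
            else:  # ionic
                hit = self._min_dist_within(coords, idx["a"], idx["b"], c.ionic_dist)
            if key in out:
                out[key] |= hit
            else:
                out[key] = hit
        return out


def detect_contacts(
    snapshot: Snapshot,
    scheme: FragmentScheme,
    role_map: ResidueRoleMap,
    criteria: ContactCriteria | None = None,
    fragments: Sequence[str] | None = None,
) -> set[tuple[str, str, str]]:
    """Typed contacts present in one frame as ``(fragment, role, type)``."""
    criteria = criteria or ContactCriteria()
    if fragments is not None:
        for label in fragments:
            if scheme.fragment_atoms(label).size == 0:
                raise ValidationError(f"fragment {label!r} has no atoms")
    engine = _ContactEngine(
        snapshot.atoms, snapshot.positions, scheme, role_map, criteria
    )
    hits = engine.evaluate(snapshot.positions[None])
    found = {key for key, arr in hits.items() if arr[0]}
    if fragments is not None:
        found = {k for k in found if k[0] in fragments}
    return found


def contact_frequencies(
    pool: TrajectoryPool,
    scheme: FragmentScheme,
    role_map: ResidueRoleMap,
    criteria: ContactCriteria | None = None,
    include_zero: bool = False,
) -> pd.DataFrame:
    """Replica-aggregated contact frequencies over a snapshot pool.

    One row per ``(fragment, residue, type)`` with per-replica frequencies,
    their mean and the SEM across replicas (NaN for a single replica).
    Rows never observed are omitted unless ``include_zero``.
    """
    criteria = criteria or ContactCriteria()
    engine = _ContactEngine(pool.atoms, pool.coords[0], scheme, role_map, criteria)
    hits = engine.evaluate(pool.coords)
    rep_ids = list(pool.replica_ids)
    rows = []
    for (fragment, role, ctype), arr in sorted(hits.items()):
        freqs = []
        for rid in rep_ids:
            mask = pool.replicas == rid
            freqs.append(float(arr[mask].mean()))
        mean = float(np.mean(freqs))
        if not include_zero and mean == 0.0:
            continue
        sem = (
            float(np.std(freqs, ddof=1) / math.sqrt(len(freqs)))
            if len(freqs) > 1
            else math.nan
        )
        row = {
            "fragment": fragment,
            "residue": role,
            "type": ctype,
            "mean": mean,
            "sem": sem,
            "n_replicas": len(freqs),
        }
        for rid, f in zip(rep_ids, freqs):
            row[f"freq_rep{rid}"] = f
        rows.append(row)
    return pd.DataFrame(rows)


def ionic_persistence(
    pool: TrajectoryPool,
    role_map: ResidueRoleMap,
    scheme: FragmentScheme,
    criteria: ContactCriteria | None = None,
) -> float:
    """Fraction of frames with the ligand N+ within ``ionic_dist`` of a D147
    carboxylate oxygen (boundary counts as present)."""
    criteria = criteria or ContactCriteria()
    n_plus = int(scheme.protonable_nitrogen)
    resnum = role_map.residue_number("D147")
    ox = pool.residue_atom_indices(resnum, CARBOXYLATE_OXYGENS["ASP"])
    if ox.size == 0:
        raise ValidationError("D147 carboxylate oxygens (OD1/OD2) not found")
    d = np.linalg.norm(
        pool.coords[:, [n_plus], :] - pool.coords[:, ox, :], axis=2
    ).min(axis=1)
    return float(np.mean(d <= criteria.ionic_dist))


@dataclass(frozen=True)
class GeneralFeature:
    """Outcome of one binding-mode feature check; ``value`` is None when the
    feature is not applicable (e.g. no 4-axial substituent)."""

    name: str
    value: bool | None
    evidence: dict = field(default_factory=dict)


#: Partner residues per feature (fragment, partner roles, contact types).
GF_DEFINITIONS = {
    "GF2": ("n_chain", ("I296", "I322", "W293", "Y326"), ("Hy",)),
    "GF3": ("propanamide", ("I144", "L219"), ("Hy", "Hb")),
    "GF4": ("anilide_aromatic", ("C217", "I144", "V143", "W133"), ("Hy", "A")),
    "GF5": ("axial_4", ("W318",), ("Hy",)),
}


def evaluate_general_features(
    freq_table: pd.DataFrame,
    ionic: float,
    scheme: FragmentScheme,
    frequency_threshold: float = 0.5,
    min_partners: int = 1,
) -> dict[str, GeneralFeature]:
    """Evaluate the five binding-mode features of the fentanyl pose.

    GF1 holds when salt-bridge persistence reaches ``frequency_threshold``;
    GF2-GF5 hold when at least ``min_partners`` of the listed residues show a
    mean contact frequency at or above the threshold for the relevant
    fragment.  GF5 is not applicable when the ligand has no 4-axial
    substituent.
    """
    out = {
        "GF1": GeneralFeature(
            "GF1", ionic >= frequency_threshold, {"ionic_persistence": ionic}
        )
    }
    for name, (fragment, partners, types) in GF_DEFINITIONS.items():
        if scheme.fragment_atoms(fragment).size == 0:
            out[name] = GeneralFeature(name, None, {"fragment": fragment})
            continue
        sub = freq_table[
            (freq_table["fragment"] == fragment)
            & freq_table["residue"].isin(partners)
            & freq_table["type"].isin(types)
        ]
        per_partner = sub.groupby("residue")["mean"].max()
        satisfied = {
            r: float(per_partner.get(r, 0.0))
            for r in partners
        }
        n_ok = sum(v >= frequency_threshold for v in satisfied.values())
        out[name] = GeneralFeature(name, n_ok >= min_partners, satisfied)
    return out
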