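"""Per-derivative receptor/ligand characteristics computed on snapshot pools.

The pool-level summaries mirror the standard post-processing of GPCR-ligand
simulations: backbone RMSD against the run's reference structure and RMSF
about the time-mean, side-chain chi1/chi2 dihedrals of binding-site residues
averaged circularly, the ligand-N+ to D147(Cgamma) salt-bridge distance, the
D147(Cgamma)-Y326(OH) "3-7 lock" distance, and first-shell hydration counts.

Distances and hydration counts are averaged arithmetically; dihedrals use the
circular mean (direction of the resultant of unit vectors), which is the only
defensible average for angular data that may straddle the +/-180 deg seam.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._geometry import dihedral_deg, superpose, wrap_deg
from .core import FragmentScheme, ResidueRoleMap, Snapshot, TrajectoryPool, ValidationError

__all__ = [
    "StatTestResult",
    "chi_dihedral",
    "chi_series",
    "circular_mean",
    "circular_sem",
    "circular_std",
    "descriptor_summary",
    "hydration_count",
    "hydration_series",
    "kruskal_wallis",
    "lock_distance_series",
    "one_way_anova",
    "pair_distance",
    "rmsd_series",
    "rmsf",
    "saltbridge_distance_series",
]

#: Dihedral-bearing roles summarised by default.
DEFAULT_CHI_ROLES = (
    "W133", "D147", "Y148", "W293", "H297", "W318", "H319", "Y326", "Y336",
)

# chi1 is N-CA-CB-XG; the distal atom depends on residue chemistry.
_CHI1_DISTAL = {
    "ILE": "CG1", "VAL": "CG1", "THR": "OG1", "SER": "OG", "CYS": "SG",
}
# chi2 is CA-CB-CG-XD (rotamer-library convention); Asp uses the OD1 branch,
# selected by atom name.
_CHI2_DISTAL = {
    "ASP": "OD1", "ASN": "OD1", "TRP": "CD1", "TYR": "CD1", "PHE": "CD1",
    "HIS": "ND1", "MET": "SD", "LEU": "CD1", "GLU": "CD", "GLN": "CD",
    "LYS": "CD", "ARG": "CD", "PRO": "CD",
}


def _chi_atom_names(res_name: str, which: str) -> tuple[str, str, str, str]:
    res_name = res_name.upper()
    if which == "X1":
        if res_name in ("ALA", "GLY"):
            raise ValidationError(f"{res_name} has no chi1 dihedral")
        return ("N", "CA", "CB", _CHI1_DISTAL.get(res_name, "CG"))
    if which == "X2":
        if res_name == "ILE":
            return ("CA", "CB", "CG1", "CD1")
        try:
            return ("CA", "CB", "CG", _CHI2_DISTAL[res_name])
        except KeyError:
            raise ValidationError(f"{res_name} has no chi2 dihedral") from None
    raise ValidationError(f"which must be 'X1' or 'X2', got {which!r}")


def _chi_indices(
    atoms: pd.DataFrame, residue_number: int, res_name: str, which: str
) -> np.ndarray:
    names = _chi_atom_names(res_name, which)
    sub = atoms[
        (atoms["residue_number"] == residue_number)
        & (atoms["category"] == "protein")
    ]
    idx = []
    for name in names:
        hit = sub.index[sub["name"] == name]
        if len(hit) == 0:
            raise ValidationError(
                f"residue {residue_number} ({res_name}) lacks atom {name!r} "
                f"needed for {which}"
            )
        idx.append(int(hit[0]))
    return np.asarray(idx, dtype=int)


def chi_dihedral(
    snapshot: Snapshot, role_map: ResidueRoleMap, role: str, which: str = "X1"
) -> float:
    """Side-chain dihedral (degrees, (-180, 180]) of a role residue."""
    resnum = role_map.residue_number(role)
    idx = _chi_indices(snapshot.atoms, resnum, role_map.residue_name(role), which)
    a, b, c, d = snapshot.positions[idx]
    return float(dihedral_deg(a, b, c, d))


def chi_series(
    pool: TrajectoryPool, role_map: ResidueRoleMap, role: str, which: str = "X1"
) -> np.ndarray:
    """Per-frame chi dihedral over the whole pool (vectorised)."""
    resnum = role_map.residue_number(role)
    idx = _chi_indices(pool.atoms, resnum, role_map.residue_name(role), which)
    p = pool.coords[:, idx, :]
    return np.asarray(dihedral_deg(p[:, 0], p[:, 1], p[:, 2], p[:, 3]))


# ---------------------------------------------------------------------------
# Circular statistics
# ---------------------------------------------------------------------------

def _resultant(angles_deg: np.ndarray) -> tuple[float, float, float]:
    rad = np.radians(angles_deg)
    c = float(np.mean(np.cos(rad)))
    s = float(np.mean(np.sin(rad)))
    return c, s, math.hypot(c, s)


def circular_mean(angles_deg: Sequence[float]) -> float:
    """Circular mean in degrees on (-180, 180]; NaN when the mean direction is
    undefined (resultant length below 1e-6, e.g. angles uniform on the circle).
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValidationError("circular_mean of an empty sequence")
    c, s, r = _resultant(a)
    if r < 1e-6:
        return math.nan
    return float(wrap_deg(math.degrees(math.atan2(s, c))))


def circular_std(angles_deg: Sequence[float]) -> float:
    """Circular standard deviation in degrees, sqrt(-2 ln R)."""
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValidationError("circular_std of an empty sequence")
    _, _, r = _resultant(a)
    if r < 1e-12:
        return math.inf
    return float(math.degrees(math.sqrt(-2.0 * math.log(min(r, 1.0)))))


def circular_sem(angles_deg: Sequence[float]) -> float:
    """Circular standard error of the mean: circular std / sqrt(n)."""
    a = np.asarray(angles_deg, dtype=float)
    return circular_std(a) / math.sqrt(a.size)


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------

def _resolve_selection(
    pool: TrajectoryPool,
    role_map: ResidueRoleMap | None,
    helix: str | None,
    selection: np.ndarray | None,
) -> np.ndarray:
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
    elif helix is not None:
        if role_map is None:
            raise ValidationError("a role map is required to select a helix")
        sel = pool.backbone_indices(role_map.helix_range(helix))
        if sel.size == 0:
            raise ValidationError(f"helix {helix}: selection is empty")
    else:
        sel = pool.backbone_indices()
    if sel.size == 0:
        raise ValidationError("empty atom selection")
    return sel


def rmsd_series(
    pool: TrajectoryPool,
    role_map: ResidueRoleMap | None = None,
    helix: str | None = None,
    selection: np.ndarray | None = None,
    reference: np.ndarray | None = None,
    fit: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Angstrom) of a backbone selection against a reference.

    The selection defaults to the whole protein backbone; pass ``helix`` to
    restrict to one helix's residue range.  The reference defaults to the
    pool's first frame (the 0.0 ns structure when the pool carries it).  By
    default every frame is least-squares superposed onto the reference over
    the selection before the deviation is measured; ``fit=False`` gives the
    raw coordinate deviation.
    """
    sel = _resolve_selection(pool, role_map, helix, selection)
    if reference is None:
        ref = pool.coords[0, sel]
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape == (pool.n_atoms, 3):
            ref = ref[sel]
        elif ref.shape != (sel.size, 3):
            raise ValidationError(
                "reference must cover the full atom table or the selection"
            )
    out = np.empty(pool.n_frames)
    for i in range(pool.n_frames):
        mob = pool.coords[i, sel]
        if fit:
            mob = superpose(mob, ref)
        out[i] = math.sqrt(float(np.mean(np.sum((mob - ref) ** 2, axis=1))))
    return out


def rmsf(
    pool: TrajectoryPool,
    role_map: ResidueRoleMap | None = None,
    helix: str | None = None,
    selection: np.ndarray | None = None,
    fit: bool = True,
) -> tuple[np.ndarray, float]:
    """Per-atom RMSF about the time-mean position, and the selection mean.

    Frames are superposed onto the first frame over the selection, so a
    uniform rigid drift of the whole system does not register as fluctuation.
    """
    if pool.n_frames < 2:
        raise ValidationError("RMSF undefined for fewer than two frames")
    sel = _resolve_selection(pool, role_map, helix, selection)
    ref = pool.coords[0, sel]
    aligned = np.empty((pool.n_frames, sel.size, 3))
    for i in range(pool.n_frames):
        mob = pool.coords[i, sel]
        aligned[i] = superpose(mob, ref) if fit else mob
    mean_pos = aligned.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((aligned - mean_pos) ** 2, axis=2), axis=0))
    return per_atom, float(per_atom.mean())


# ---------------------------------------------------------------------------
# Distances and hydration
# ---------------------------------------------------------------------------

def pair_distance(snapshot: Snapshot, atom_a: int, atom_b: int) -> float:
    """Euclidean distance (Angstrom) between two atoms of a snapshot."""
    n = snapshot.positions.shape[0]
    for i in (atom_a, atom_b):
        if not 0 <= i < n:
            raise ValidationError(f"atom index {i} outside the atom table")
    return float(np.linalg.norm(snapshot.positions[atom_a] - snapshot.positions[atom_b]))


def _pool_pair_series(pool: TrajectoryPool, i: int, j: int) -> np.ndarray:
    return np.linalg.norm(pool.coords[:, i] - pool.coords[:, j], axis=1)


def lock_distance_series(pool: TrajectoryPool, role_map: ResidueRoleMap) -> np.ndarray:
    """Per-frame D147(Cgamma)-Y326(OH) distance, the '3-7 lock' descriptor."""
    i = pool.atom_index(role_map.residue_number("D147"), "CG")
    j = pool.atom_index(role_map.residue_number("Y326"), "OH")
    return _pool_pair_series(pool, i, j)


def saltbridge_distance_series(
    pool: TrajectoryPool, role_map: ResidueRoleMap, scheme: FragmentScheme
) -> np.ndarray:
    """Per-frame distance between the ligand's protonable nitrogen and the
    Cgamma of D147."""
    i = int(scheme.protonable_nitrogen)
    j = pool.atom_index(role_map.residue_number("D147"), "CG")
    return _pool_pair_series(pool, i, j)


def _water_membership(pool: TrajectoryPool) -> tuple[np.ndarray, np.ndarray]:
    """(water atom indices, molecule label per water atom)."""
    groups = pool.water_molecules()
    idx = np.concatenate(groups) if groups else np.empty(0, dtype=int)
    labels = np.concatenate(
        [np.full(len(g), k, dtype=int) for k, g in enumerate(groups)]
    ) if groups else np.empty(0, dtype=int)
    return idx, labels


def hydration_series(
    pool: TrajectoryPool,
    role_map: ResidueRoleMap,
    role: str,
    cutoff: float = 5.0,
) -> np.ndarray:
    """Per-frame count of distinct water molecules with at least one atom
    within ``cutoff`` Angstrom of any atom of the role residue."""
    resnum = role_map.residue_number(role)
    res_idx = pool.residue_atom_indices(resnum)
    if res_idx.size == 0:
        raise ValidationError(f"role {role}: residue {resnum} absent from pool")
    wat_idx, wat_label = _water_membership(pool)
    if wat_idx.size == 0:
        return np.zeros(pool.n_frames, dtype=int)
    n_mol = int(wat_label.max()) + 1
    counts = np.empty(pool.n_frames, dtype=int)
    cutoff2 = cutoff * cutoff
    chunk = max(1, int(2e6 // (res_idx.size * wat_idx.size)) or 1)
    for start in range(0, pool.n_frames, chunk):
        sl = slice(start, min(start + chunk, pool.n_frames))
        rp = pool.coords[sl][:, res_idx, None, :]
        wp = pool.coords[sl][:, None, wat_idx, :]
        within = np.any(((rp - wp) ** 2).sum(-1) <= cutoff2, axis=1)  # (f, W)
        for k, row in enumerate(within):
            counts[start + k] = np.unique(wat_label[row]).size if row.any() else 0
    return counts


def hydration_count(
    snapshot: Snapshot,
    role_map: ResidueRoleMap,
    role: str,
    cutoff: float = 5.0,
) -> int:
    """Water molecules within ``cutoff`` of the role residue in one frame.

    Counting is molecule-level: a water whose only in-range atom is a
    hydrogen still counts once.
    """
    pool = TrajectoryPool(
        atoms=snapshot.atoms,
        coords=snapshot.positions[None],
        times=[snapshot.time],
        replicas=[snapshot.replica_id],
    )
    return int(hydration_series(pool, role_map, role, cutoff)[0])


# ---------------------------------------------------------------------------
# Group comparison tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatTestResult:
    test: str
    statistic: float
    pvalue: float
    alpha: float

    @property
    def reject(self) -> bool:
        return self.pvalue < self.alpha


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValidationError("at least two groups required")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for k, g in enumerate(arrays):
        if g.size < 2:
            raise ValidationError(f"group {k} has fewer than two observations")
    return arrays


def kruskal_wallis(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> StatTestResult:
    """Kruskal-Wallis H test across groups at significance level ``alpha``."""
    arrays = _check_groups(groups)
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        # fully tied data carry no evidence against equal medians
        return StatTestResult("kruskal-wallis", 0.0, 1.0, alpha)
    stat, p = stats.kruskal(*arrays)
    return StatTestResult("kruskal-wallis", float(stat), float(p), alpha)


def one_way_anova(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> StatTestResult:
    """One-way ANOVA F test across groups at significance level ``alpha``."""
    arrays = _check_groups(groups)
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        return StatTestResult("one-way-anova", 0.0, 1.0, alpha)
    stat, p = stats.f_oneway(*arrays)
    return StatTestResult("one-way-anova", float(stat), float(p), alpha)


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------

def descriptor_summary(
    pools: Mapping[str, TrajectoryPool],
    role_map: ResidueRoleMap,
    schemes: Mapping[str, FragmentScheme] | None = None,
    chi_roles: Sequence[str] = DEFAULT_CHI_ROLES,
    hydration_roles: Sequence[str] = ("D114", "Y336"),
    hydration_cutoff: float = 5.0,
) -> pd.DataFrame:
    """One row per derivative: arithmetic means for RMSD/RMSF, distances and
    hydration counts, circular means (with circular SEM) for dihedrals."""
    rows = []
    for did, pool in pools.items():
        row: dict[str, float | str] = {"derivative_id": did}
        row["rmsd_backbone_mean"] = float(np.mean(rmsd_series(pool, role_map)))
        row["rmsf_backbone_mean"] = rmsf(pool, role_map)[1]
        for helix in sorted(role_map.helix_ranges):
            row[f"rmsd_{helix}_mean"] = float(
                np.mean(rmsd_series(pool, role_map, helix=helix))
            )
            row[f"rmsf_{helix}_mean"] = rmsf(pool, role_map, helix=helix)[1]
        for role in chi_roles:
            for which in ("X1", "X2"):
                series = chi_series(pool, role_map, role, which)
                row[f"{role}_{which}_circmean"] = circular_mean(series)
                row[f"{role}_{which}_circsem"] = circular_sem(series)
        row["lock_d147_y326_mean"] = float(
            np.mean(lock_distance_series(pool, role_map))
        )
        if schemes is not None and did in schemes:
            row["saltbridge_n_d147_mean"] = float(
                np.mean(saltbridge_distance_series(pool, role_map, schemes[did]))
            )
        for role in hydration_roles:
            row[f"hydration_{role}_mean"] = float(
                np.mean(hydration_series(pool, role_map, role, hydration_cutoff))
            )
        rows.append(row)
    return pd.DataFrame(rows)
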