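"""Seeded generators for toy receptor-ligand snapshot pools and SAR/score
tables with known ground truth.

The pool generator emulates the *statistical* structure of production-run
output -- not the physics.  Per frame it realises, in actual coordinates:

* backbone positions for seven helices with isotropic Gaussian fluctuation,
* side chains of the binding-site role residues rebuilt from sampled chi1/chi2
  dihedrals (wrapped-normal law per residue),
* a ligand whose fragment probe atoms are placed inside or outside the
  type-specific contact cutoffs with a prescribed per-frame probability,
* the D147 salt bridge and the D147-Y326 'lock' distance with prescribed
  presence/mean, and
* Poisson-distributed first-shell waters around the hydration residues.

Because contacts are realised geometrically rather than by labelling, the
contact detector is tested end-to-end against the generator's targets.
Every generator returns its ground truth next to the data, and the same seed
reproduces bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._geometry import place_atom, wrap_deg
from .core import (
    FRAGMENT_LABELS,
    FragmentScheme,
    ResidueRoleMap,
    TrajectoryPool,
    ValidationError,
)

__all__ = [
    "GenerationError",
    "SARSpec",
    "ScoreSpec",
    "SyntheticPool",
    "SyntheticSpec",
    "generate_pool",
    "generate_sar_table",
    "generate_score_table",
]


class GenerationError(ValueError):
    """Raised for infeasible generation requests."""


# -- defaults: the study conditions the generator emulates -------------------

#: Circular (mean, sd) in degrees per (role, chi) pair.
DEFAULT_DIHEDRAL_LAWS: dict[tuple[str, str], tuple[float, float]] = {
    ("W133", "X1"): (-70.0, 12.0), ("W133", "X2"): (-100.0, 15.0),
    ("D147", "X1"): (-65.0, 12.0), ("D147", "X2"): (-20.0, 20.0),
    ("Y148", "X1"): (-177.0, 12.0), ("Y148", "X2"): (65.0, 15.0),
    ("W293", "X1"): (-70.0, 12.0), ("W293", "X2"): (-100.0, 15.0),
    ("H297", "X1"): (-65.0, 12.0), ("H297", "X2"): (-80.0, 15.0),
    ("W318", "X1"): (-70.0, 12.0), ("W318", "X2"): (-105.0, 15.0),
    ("H319", "X1"): (-60.0, 12.0), ("H319", "X2"): (80.0, 15.0),
    ("Y326", "X1"): (-65.0, 12.0), ("Y326", "X2"): (-95.0, 15.0),
    ("Y336", "X1"): (-65.0, 12.0), ("Y336", "X2"): (100.0, 15.0),
}

#: Target per-frame contact probabilities, (fragment, role, type, p); the
#: pattern satisfies all five binding-mode features of the parent pose.
DEFAULT_CONTACT_TARGETS: tuple[tuple[str, str, str, float], ...] = (
    ("piperidine", "Y148", "Hy", 0.8),
    ("piperidine", "W318", "Hy", 0.6),
    ("piperidine", "I322", "Hy", 0.7),
    ("piperidine", "Q124", "Hy", 0.4),
    ("n_chain", "I296", "Hy", 0.9),
    ("n_chain", "I322", "Hy", 0.9),
    ("n_chain", "W293", "Hy", 0.5),
    ("n_chain", "Y326", "Hy", 0.8),
    ("propanamide", "I144", "Hy", 0.8),
    ("propanamide", "L219", "Hy", 0.7),
    ("propanamide", "L232", "Hy", 0.35),
    ("propanamide", "T218", "Hb", 0.3),
    ("anilide_aromatic", "C217", "Hy", 0.8),
    ("anilide_aromatic", "I144", "Hy", 0.7),
    ("anilide_aromatic", "V143", "Hy", 0.7),
    ("anilide_aromatic", "W133", "A", 0.3),
    ("axial_4", "W318", "Hy", 0.7),
    ("axial_4", "I322", "Hy", 0.5),
    ("axial_4", "S55", "Hb", 0.3),
)

DEFAULT_HYDRATION_RATES = {"D114": 4.0, "Y336": 2.5}

#: Per-coordinate backbone noise sd (Angstrom); sigma*sqrt(3) ~= 0.93 A,
#: the backbone RMSF level the pools emulate.
DEFAULT_HELIX_SIGMA = 0.537

DEFAULT_BODY_SIZES = {
    "piperidine": 6, "n_chain": 6, "anilide_aromatic": 6,
    "propanamide": 4, "axial_4": 3,
}


@dataclass
class SyntheticSpec:
    """Conditions for one synthetic derivative pool.

    Defaults follow the pooled-production-run setup all analyses assume:
    three replicas, the final 10 ns of a 50 ns run, 100 snapshots per ns.
    """

    seed: int = 0
    derivative_id: str = "SYN01"
    n_replicas: int = 3
    tail_ns: float = 10.0
    per_ns: int = 100
    run_length_ns: float = 50.0
    dihedral_laws: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DIHEDRAL_LAWS)
    )
    hydration_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HYDRATION_RATES)
    )
    contact_targets: tuple[tuple[str, str, str, float], ...] = (
        DEFAULT_CONTACT_TARGETS
    )
    saltbridge_presence: float = 0.99
    lock_mean: float = 5.6
    lock_sd: float = 0.25
    helix_sigma: float = DEFAULT_HELIX_SIGMA
    body_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_BODY_SIZES)
    )
    role_map: ResidueRoleMap = field(default_factory=ResidueRoleMap)

    def __post_init__(self) -> None:
        if self.n_replicas < 1:
            raise ValidationError("n_replicas must be >= 1")
        if not 0 <= self.saltbridge_presence <= 1:
            raise ValidationError("saltbridge_presence must be in [0, 1]")
        for _, _, _, p in self.contact_targets:
            if not 0 <= p <= 1:
                raise ValidationError("contact probabilities must be in [0, 1]")
        for mu, sd in self.dihedral_laws.values():
            if sd < 0:
                raise ValidationError("dihedral sd must be >= 0")
        for lam in self.hydration_rates.values():
            if lam < 0:
                raise ValidationError("hydration rates must be >= 0")
        if self.helix_sigma < 0 or self.lock_sd < 0:
            raise ValidationError("noise amplitudes must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.n_replicas * int(round(self.tail_ns * self.per_ns))


@dataclass
class SyntheticPool:
    pool: TrajectoryPool
    scheme: FragmentScheme
    role_map: ResidueRoleMap
    truth: dict


# -- side-chain construction recipes ----------------------------------------
# step: (atom name, (ref A, ref B, ref C), bond, angle, dihedral spec)
# dihedral spec: "chi1" / "chi2" (optionally +offset) or a fixed number.
_SIDE_RECIPES: dict[str, list[tuple]] = {
    "ASP": [("CG", ("N", "CA", "CB"), 1.52, 114.0, "chi1"),
            ("OD1", ("CA", "CB", "CG"), 1.25, 118.0, "chi2"),
            ("OD2", ("CA", "CB", "CG"), 1.25, 118.0, "chi2+180")],
    "TYR": [("CG", ("N", "CA", "CB"), 1.51, 114.0, "chi1"),
            ("CD1", ("CA", "CB", "CG"), 1.39, 120.0, "chi2")],
    "TRP": [("CG", ("N", "CA", "CB"), 1.50, 114.0, "chi1"),
            ("CD1", ("CA", "CB", "CG"), 1.37, 127.0, "chi2")],
    "HIS": [("CG", ("N", "CA", "CB"), 1.50, 114.0, "chi1"),
            ("ND1", ("CA", "CB", "CG"), 1.38, 122.0, "chi2")],
    "ILE": [("CG1", ("N", "CA", "CB"), 1.53, 111.0, "chi1"),
            ("CG2", ("N", "CA", "CB"), 1.53, 111.0, "chi1+122"),
            ("CD1", ("CA", "CB", "CG1"), 1.53, 113.0, "chi2")],
    "VAL": [("CG1", ("N", "CA", "CB"), 1.53, 111.0, "chi1"),
            ("CG2", ("N", "CA", "CB"), 1.53, 111.0, "chi1+122")],
    "LEU": [("CG", ("N", "CA", "CB"), 1.53, 116.0, "chi1"),
            ("CD1", ("CA", "CB", "CG"), 1.53, 111.0, "chi2"),
            ("CD2", ("CA", "CB", "CG"), 1.53, 111.0, "chi2+122")],
    "CYS": [("SG", ("N", "CA", "CB"), 1.81, 114.0, "chi1")],
    "THR": [("OG1", ("N", "CA", "CB"), 1.42, 109.0, "chi1"),
            ("CG2", ("N", "CA", "CB"), 1.53, 111.0, "chi1+122")],
    "SER": [("OG", ("N", "CA", "CB"), 1.42, 110.0, "chi1")],
    "GLN": [("CG", ("N", "CA", "CB"), 1.52, 114.0, "chi1"),
            ("CD", ("CA", "CB", "CG"), 1.52, 112.0, "chi2"),
            ("OE1", ("CB", "CG", "CD"), 1.23, 121.0, 0.0),
            ("NE2", ("CB", "CG", "CD"), 1.33, 117.0, 180.0)],
    "GLU": [("CG", ("N", "CA", "CB"), 1.52, 114.0, "chi1"),
            ("CD", ("CA", "CB", "CG"), 1.52, 112.0, "chi2"),
            ("OE1", ("CB", "CG", "CD"), 1.25, 118.0, 0.0),
            ("OE2", ("CB", "CG", "CD"), 1.25, 118.0, 180.0)],
    "MET": [("CG", ("N", "CA", "CB"), 1.52, 114.0, "chi1"),
            ("SD", ("CA", "CB", "CG"), 1.81, 112.0, "chi2"),
            ("CE", ("CB", "CG", "SD"), 1.79, 100.0, -75.0)],
}

# cyclic ring orders; the first two are already placed by the recipe.
_RING_ORDERS = {
    "TYR": ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
    "PHE": ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
    "TRP": ("CG", "CD1", "NE1", "CE2", "CD2"),
    "HIS": ("CG", "ND1", "CE1", "NE2", "CD2"),
}

_ELEMENT_FROM_NAME = {
    "N": "N", "O": "O", "S": "S",
}


def _element_of(atom_name: str) -> str:
    return _ELEMENT_FROM_NAME.get(atom_name[0], atom_name[0])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return (
        v * c
        + np.cross(axis, v) * s
        + axis * np.sum(axis * v, axis=-1, keepdims=True) * (1 - c)
    )


def _complete_ring(
    built: dict[str, np.ndarray], res_name: str
) -> dict[str, np.ndarray]:
    """Place the remaining ring vertices of an aromatic side chain from its
    first two (CG and the chi2 atom), keeping the polygon planar."""
    order = _RING_ORDERS[res_name]
    m = len(order)
    v0, v1 = built[order[0]], built[order[1]]
    anti = built["CB"]
    bond = np.linalg.norm(v1 - v0, axis=-1, keepdims=True)
    rho = bond / (2 * math.sin(math.pi / m))
    h = np.sqrt(np.maximum(rho**2 - (bond / 2) ** 2, 0.0))
    mid = 0.5 * (v0 + v1)
    t = _unit(v1 - v0)
    n = _unit(np.cross(t, v0 - anti))
    perp = np.cross(n, t)
    side = np.sign(np.sum(perp * (mid - anti), axis=-1, keepdims=True))
    side[side == 0] = 1.0
    centre = mid + side * h * perp
    a0 = v0 - centre
    step = 2 * math.pi / m
    # orient the rotation so one step maps v0 onto v1
    fwd = centre + _rodrigues(a0, n, step)
    err_fwd = np.linalg.norm(fwd - v1, axis=-1).mean()
    bwd = centre + _rodrigues(a0, n, -step)
    err_bwd = np.linalg.norm(bwd - v1, axis=-1).mean()
    sgn = 1.0 if err_fwd <= err_bwd else -1.0
    out = {}
    for k, name in enumerate(order[2:], start=2):
        out[name] = centre + _rodrigues(a0, n, sgn * step * k)
    out["_ring_centre"] = centre
    return out


class _PoolBuilder:
    """Accumulates atoms with per-frame coordinates."""

    def __init__(self, n_frames: int) -> None:
        self.n_frames = n_frames
        self.rows: list[dict] = []
        self.coords: list[np.ndarray] = []

    def add(self, row: dict, coords: np.ndarray) -> int:
        coords = np.asarray(coords, dtype=float)
        if coords.shape == (3,):
            coords = np.broadcast_to(coords, (self.n_frames, 3)).copy()
        if coords.shape != (self.n_frames, 3):
            raise GenerationError("bad coordinate block shape")
        self.rows.append(row)
        self.coords.append(coords)
        return len(self.rows) - 1

    def frame(self) -> tuple[pd.DataFrame, np.ndarray]:
        atoms = pd.DataFrame(self.rows)
        coords = np.stack(self.coords, axis=1)  # (F, n_atoms, 3)
        return atoms, coords


def _protein_row(name: str, resnum: int, res_name: str) -> dict:
    return {
        "name": name,
        "element": _element_of(name),
        "residue_number": resnum,
        "residue_name": res_name,
        "chain": "A",
        "category": "protein",
    }


def _sample_chi(
    rng: np.random.Generator, laws: Mapping, role: str, which: str, n: int
) -> np.ndarray:
    """Wrapped-normal sample (degrees) for one chi angle; residues without a
    declared law sit at a fixed rotamer."""
    default = {"X1": -65.0, "X2": -60.0}[which]
    mu, sd = laws.get((role, which), (default, 0.0))
    if sd == 0:
        return np.full(n, mu)
    return np.asarray(wrap_deg(mu + rng.normal(0.0, sd, n)))


# geometric placement bands (Angstrom): inside / outside the type cutoffs,
# with margins large enough that neighbouring residue atoms cannot flip the
# verdict (role anchors sit >= 18 A apart on the placement circle).
_PLACEMENT = {
    "Hy": ((3.0, 4.3), (9.5, 11.0)),
    "Hb": ((2.7, 3.3), (9.0, 10.5)),
    "A": ((4.2, 5.2), (10.0, 11.5)),
}
_IONIC_IN = (2.65, 3.2)
_IONIC_OUT = (6.8, 7.8)

_HB_ACCEPTOR = {"SER": "OG", "THR": "OG1", "TYR": "OH"}

# first entries of the apolar table, used as Hy anchors
_HY_ANCHOR = {
    "ALA": "CB", "VAL": "CB", "LEU": "CB", "ILE": "CB", "MET": "CB",
    "PHE": "CB", "TRP": "CB", "TYR": "CB", "PRO": "CB", "THR": "CG2",
    "CYS": "CB", "LYS": "CB", "ARG": "CB", "GLN": "CB", "GLU": "CB",
    "ASP": "CB", "ASN": "CB", "HIS": "CB",
}


def generate_pool(spec: SyntheticSpec) -> SyntheticPool:
    """Build one synthetic snapshot pool with its fragment scheme and truth."""
    rng = np.random.default_rng(spec.seed)
    role_map = spec.role_map
    n_per_rep = int(round(spec.tail_ns * spec.per_ns))
    n_frames = spec.n_replicas * n_per_rep
    if n_frames < 1:
        raise ValidationError("empty pool requested")
    t_single = spec.run_length_ns - spec.tail_ns + np.arange(n_per_rep) / spec.per_ns
    times = np.tile(t_single, spec.n_replicas)
    replicas = np.repeat(np.arange(1, spec.n_replicas + 1), n_per_rep)

    b = _PoolBuilder(n_frames)
    role_numbers = set(role_map.roles.values())

    # ---- helix backbones (pure-backbone residues) ----------------------
    backbone_atoms: list[int] = []
    helix_names = sorted(role_map.helix_ranges)
    for k, helix in enumerate(helix_names):
        lo, hi = role_map.helix_range(helix)
        ang = 2 * math.pi * k / len(helix_names)
        centre = np.array([200.0 * math.cos(ang), 200.0 * math.sin(ang), 0.0])
        for resnum in range(lo, hi + 1):
            if resnum in role_numbers:
                continue
            ca = centre + np.array([0.0, 0.0, 1.5 * (resnum - lo)])
            for name, off in (
                ("N", (-1.33, 0.45, 0.0)),
                ("CA", (0.0, 0.0, 0.0)),
                ("C", (1.20, 0.80, 0.0)),
                ("O", (1.60, 1.91, 0.0)),
            ):
                backbone_atoms.append(
                    b.add(_protein_row(name, resnum, "ALA"), ca + np.array(off))
                )

    # ---- role residues (full local build) ------------------------------
    anchors: dict[str, np.ndarray] = {"D147": np.zeros(3)}
    others = sorted(r for r in role_map.roles if r != "D147")
    for k, role in enumerate(others):
        ang = 2 * math.pi * k / len(others)
        anchors[role] = np.array(
            [60.0 * math.cos(ang), 60.0 * math.sin(ang), 0.0]
        )

    res_atoms: dict[str, dict[str, np.ndarray]] = {}
    res_index: dict[str, dict[str, int]] = {}
    for role in sorted(role_map.roles):
        resnum = role_map.residue_number(role)
        res_name = role_map.residue_name(role)
        if res_name not in _SIDE_RECIPES:
            raise GenerationError(f"no side-chain recipe for {res_name} ({role})")
        ca = anchors[role]
        base = {
            "N": ca + np.array([1.46, 0.0, 0.0]),
            "CA": ca,
            "C": ca + np.array([-0.55, 1.42, 0.0]),
            "O": ca + np.array([-0.15, 2.58, 0.45]),
        }
        built: dict[str, np.ndarray] = {}
        idx: dict[str, int] = {}
        for name in ("N", "CA", "C", "O"):
            i = b.add(_protein_row(name, resnum, res_name), base[name])
            backbone_atoms.append(i)
            built[name] = b.coords[i]  # noisy later, arrays shared by ref
            idx[name] = i
        res_atoms[role] = built
        res_index[role] = idx

    # apply backbone noise in one deterministic draw
    if spec.helix_sigma > 0 and backbone_atoms:
        noise = rng.normal(0.0, spec.helix_sigma, (len(backbone_atoms), n_frames, 3))
        for j, i in enumerate(backbone_atoms):
            b.coords[i] = b.coords[i] + noise[j]
    # refresh role references to the noisy arrays
    for role in res_atoms:
        for name in ("N", "CA", "C", "O"):
            res_atoms[role][name] = b.coords[res_index[role][name]]

    # side chains rebuilt per frame from the (noisy) backbone
    for role in sorted(role_map.roles):
        resnum = role_map.residue_number(role)
        res_name = role_map.residue_name(role)
        built = res_atoms[role]
        chi1 = _sample_chi(rng, spec.dihedral_laws, role, "X1", n_frames)
        chi2 = _sample_chi(rng, spec.dihedral_laws, role, "X2", n_frames)
        # CB from fixed internal coordinates off the backbone
        built["CB"] = place_atom(built["N"], built["C"], built["CA"], 1.53, 111.0, 122.5)
        b.add(_protein_row("CB", resnum, res_name), built["CB"])
        for name, refs, bond, angle, dspec in _SIDE_RECIPES[res_name]:
            if isinstance(dspec, str):
                basechi = chi1 if dspec.startswith("chi1") else chi2
                off = float(dspec.split("+")[1]) if "+" in dspec else 0.0
                dih = wrap_deg(basechi + off)
            else:
                dih = np.full(n_frames, float(dspec))
            pos = place_atom(
                built[refs[0]], built[refs[1]], built[refs[2]], bond, angle, dih
            )
            built[name] = pos
            b.add(_protein_row(name, resnum, res_name), pos)
        if res_name in _RING_ORDERS:
            extra = _complete_ring(built, res_name)
            centre = extra.pop("_ring_centre")
            for name, pos in extra.items():
                built[name] = pos
                b.add(_protein_row(name, resnum, res_name), pos)
            built["_ring_centre"] = centre
            if res_name == "TYR" and role != "Y326":
                cz = built["CZ"]
                oh = cz + 1.36 * _unit(cz - centre)
                built["OH"] = oh
                b.add(_protein_row("OH", resnum, "TYR"), oh)

    # the Y326 hydroxyl realises the lock-distance law around D147's CG
    d147_cg = res_atoms["D147"]["CG"]
    lock_d = rng.normal(spec.lock_mean, spec.lock_sd, n_frames)
    lock_d = np.clip(lock_d, 0.1, None)
    lock_u = _unit(rng.normal(size=(n_frames, 3)))
    y326_num = role_map.residue_number("Y326")
    oh_pos = d147_cg + lock_d[:, None] * lock_u
    res_atoms["Y326"]["OH"] = oh_pos
    b.add(_protein_row("OH", y326_num, "TYR"), oh_pos)

    # ---- ligand --------------------------------------------------------
    lig_centre = np.array([12.0, 0.0, 0.0])
    frag_offsets = {
        "piperidine": np.array([0.0, 0.0, 0.0]),
        "n_chain": np.array([0.0, 4.0, 0.0]),
        "anilide_aromatic": np.array([0.0, -4.0, 0.0]),
        "propanamide": np.array([0.0, 0.0, 4.0]),
        "axial_4": np.array([0.0, 0.0, -4.0]),
    }
    fragments: dict[str, list[int]] = {label: [] for label in FRAGMENT_LABELS}
    bonds: list[tuple[int, int]] = []
    rings: list[list[int]] = []

    def lig_row(name: str, element: str) -> dict:
        return {
            "name": name, "element": element, "residue_number": 900,
            "residue_name": "LIG", "chain": "L", "category": "ligand",
        }

    serial = 0
    for label in FRAGMENT_LABELS:
        n_body = int(spec.body_sizes.get(label, 0))
        prev = None
        for j in range(n_body):
            serial += 1
            pos = (
                lig_centre + frag_offsets[label]
                + rng.normal(0.0, 0.8, 3)
            )
            i = b.add(lig_row(f"C{serial}", "C"), pos)
            fragments[label].append(i)
            if prev is not None:
                bonds.append((prev, i))
            prev = i

    # protonable nitrogen: realises the salt bridge to D147's carboxylate
    if not fragments["piperidine"]:
        raise GenerationError("piperidine fragment must have body atoms")
    sb_present = rng.random(n_frames) < spec.saltbridge_presence
    d_in = rng.uniform(*_IONIC_IN, n_frames)
    d_out = rng.uniform(*_IONIC_OUT, n_frames)
    d_sb = np.where(sb_present, d_in, d_out)
    od1 = res_atoms["D147"]["OD1"]
    n_pos = od1 + d_sb[:, None] * np.array([1.0, 0.0, 0.0])
    serial += 1
    n_idx = b.add(lig_row(f"N{serial}", "N"), n_pos)
    fragments["piperidine"].append(n_idx)
    bonds.append((fragments["piperidine"][0], n_idx))

    # contact probes
    realized: dict[tuple[str, str, str], np.ndarray] = {}
    for fragment, role, ctype, p in spec.contact_targets:
        if fragment not in FRAGMENT_LABELS:
            raise GenerationError(f"unknown fragment {fragment!r}")
        if role not in role_map.roles:
            raise GenerationError(f"unknown role {role!r}")
        res_name = role_map.residue_name(role)
        built = res_atoms[role]
        u = _unit(anchors[role]) if np.any(anchors[role]) else np.array([1.0, 0.0, 0.0])
        present = rng.random(n_frames) < p
        if ctype not in _PLACEMENT:
            raise GenerationError(f"cannot realise contact type {ctype!r}")
        (in_lo, in_hi), (out_lo, out_hi) = _PLACEMENT[ctype]
        dist = np.where(
            present,
            rng.uniform(in_lo, in_hi, n_frames),
            rng.uniform(out_lo, out_hi, n_frames),
        )
        if ctype == "Hy":
            anchor_name = _HY_ANCHOR.get(res_name)
            if anchor_name is None or anchor_name not in built:
                raise GenerationError(f"{role}: no apolar anchor for a Hy probe")
            pos = built[anchor_name] + dist[:, None] * u
            serial += 1
            i = b.add(lig_row(f"C{serial}", "C"), pos)
            if fragments[fragment]:
                bonds.append((fragments[fragment][0], i))
            fragments[fragment].append(i)
        elif ctype == "Hb":
            acc_name = _HB_ACCEPTOR.get(res_name, "O")
            if acc_name not in built:
                raise GenerationError(f"{role}: no acceptor atom for an Hb probe")
            acc = built[acc_name]
            o_pos = acc + dist[:, None] * u
            h_pos = o_pos + 0.98 * _unit(acc - o_pos)
            serial += 1
            i_o = b.add(lig_row(f"O{serial}", "O"), o_pos)
            serial += 1
            i_h = b.add(lig_row(f"H{serial}", "H"), h_pos)
            if fragments[fragment]:
                bonds.append((fragments[fragment][0], i_o))
            fragments[fragment].append(i_o)
            fragments[fragment].append(i_h)
            bonds.append((i_o, i_h))
        else:  # aromatic ring probe
            if "_ring_centre" not in built:
                raise GenerationError(f"{role}: residue has no aromatic ring")
            centre = built["_ring_centre"] + dist[:, None] * u
            e1 = np.array([0.0, 0.0, 1.0])
            e2 = _unit(np.cross(e1, u))
            ring_idx = []
            for k in range(6):
                ang = 2 * math.pi * k / 6
                pos = centre + 1.39 * (math.cos(ang) * e1 + math.sin(ang) * e2)
                serial += 1
                i = b.add(lig_row(f"C{serial}", "C"), pos)
                fragments[fragment].append(i)
                ring_idx.append(i)
            for k in range(6):
                bonds.append((ring_idx[k], ring_idx[(k + 1) % 6]))
            rings.append(ring_idx)
        realized[(fragment, role, ctype)] = present

    # ---- waters --------------------------------------------------------
    for w_slot, (role, lam) in enumerate(sorted(spec.hydration_rates.items())):
        if role not in role_map.roles:
            raise GenerationError(f"hydration role {role!r} not in role map")
        counts = rng.poisson(lam, n_frames) if lam > 0 else np.zeros(n_frames, int)
        n_max = int(counts.max()) if counts.size else 0
        res_pos = np.stack(
            [v for k, v in sorted(res_atoms[role].items()) if not k.startswith("_")],
            axis=1,
        )  # (F, nA, 3)
        park = np.array([500.0 + 40.0 * w_slot, 500.0, 500.0])
        for j in range(n_max):
            active = counts > j
            pick = rng.integers(0, res_pos.shape[1], n_frames)
            base_atom = np.take_along_axis(
                res_pos, pick[:, None, None].repeat(3, axis=2), axis=1
            )[:, 0, :]
            direction = _unit(rng.normal(size=(n_frames, 3)))
            radius = rng.uniform(2.6, 4.7, n_frames)
            o_pos = base_atom + radius[:, None] * direction
            parked = park + np.array([10.0 * j, 0.0, 0.0])
            o_pos = np.where(active[:, None], o_pos, parked)
            resnum = 2000 + 100 * w_slot + j
            for name, elem, off in (
                ("OW", "O", (0.0, 0.0, 0.0)),
                ("HW1", "H", (0.96, 0.0, 0.0)),
                ("HW2", "H", (-0.24, 0.93, 0.0)),
            ):
                b.add(
                    {
                        "name": name, "element": elem, "residue_number": resnum,
                        "residue_name": "HOH", "chain": "W", "category": "water",
                    },
                    o_pos + np.array(off),
                )
        realized[("hydration", role, "count")] = counts

    atoms, coords = b.frame()
    pool = TrajectoryPool(
        atoms=atoms,
        coords=coords,
        times=times,
        replicas=replicas,
        derivative_id=spec.derivative_id,
    )
    scheme = FragmentScheme(
        fragments={k: v for k, v in fragments.items() if v},
        protonable_nitrogen=n_idx,
        aromatic_rings=rings,
        bonds=bonds,
    )
    truth = {
        "seed": spec.seed,
        "derivative_id": spec.derivative_id,
        "n_frames": n_frames,
        "dihedral_laws": {
            f"{role}_{which}": list(law)
            for (role, which), law in spec.dihedral_laws.items()
        },
        "hydration_rates": dict(spec.hydration_rates),
        "contact_targets": [list(t) for t in spec.contact_targets],
        "realized_contact_frequency": {
            f"{f}|{r}|{t}": float(np.mean(v))
            for (f, r, t), v in realized.items()
            if t not in ("count",)
        },
        "saltbridge_presence": spec.saltbridge_presence,
        "realized_saltbridge_presence": float(np.mean(sb_present)),
        "lock_mean": spec.lock_mean,
        "lock_sd": spec.lock_sd,
        "helix_sigma": spec.helix_sigma,
    }
    return SyntheticPool(pool=pool, scheme=scheme, role_map=role_map, truth=truth)


# ---------------------------------------------------------------------------
# SAR tables
# ---------------------------------------------------------------------------

@dataclass
class SARSpec:
    """Volume-affinity table with a known nonmonotone law.

    The default grid and slopes keep the per-step signal about twice the
    noise sd, the regime in which a breakpoint is identifiable from two
    dozen compounds.
    """

    model: str = "two_segment"
    n: int = 24
    x_min: float = 0.0
    x_max: float = 1150.0
    breakpoint: float = 600.0
    ascending_slope: float = 0.008
    descending_slope: float = -0.006
    peak_y: float = 9.0
    curvature: float = -5.0e-6
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("two_segment", "quadratic"):
            raise ValidationError(f"unknown SAR model {self.model!r}")
        if self.n < 3:
            raise ValidationError("need at least 3 points")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")


def generate_sar_table(spec: SARSpec) -> tuple[pd.DataFrame, dict]:
    """Sample (volume, pIC50) pairs from the chosen law plus Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    x = np.linspace(spec.x_min, spec.x_max, spec.n)
    if spec.model == "two_segment":
        y = np.where(
            x < spec.breakpoint,
            spec.peak_y + spec.ascending_slope * (x - spec.breakpoint),
            spec.peak_y + spec.descending_slope * (x - spec.breakpoint),
        )
        truth = {
            "model": "two_segment",
            "breakpoint": spec.breakpoint,
            "ascending_slope": spec.ascending_slope,
            "descending_slope": spec.descending_slope,
            "peak_y": spec.peak_y,
        }
    else:
        a = spec.curvature
        v = spec.breakpoint
        y = spec.peak_y + a * (x - v) ** 2
        truth = {
            "model": "quadratic",
            "a": a,
            "b": -2 * a * v,
            "c": a * v * v + spec.peak_y,
            "vertex": v,
        }
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, spec.n)
    table = pd.DataFrame({"volume": x, "pic50": y})
    truth.update({"noise_sd": spec.noise_sd, "n": spec.n, "seed": spec.seed})
    return table, truth


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

@dataclass
class ScoreSpec:
    """Per-snapshot scoring-function component tables with known weights."""

    n_compounds: int = 16
    n_snapshots: int = 50
    n_replicas: int = 3
    component_weights: dict[str, float] = field(
        default_factory=lambda: {"LIPSCO": 0.9, "HBOND": 0.3, "ROT": -0.2}
    )
    intercept: float = 7.5
    noise_sd: float = 0.0
    jitter_sd: float = 0.0
    function: str = "SYNSCORE"
    direction: str = "maximize"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.component_weights) < 2:
            raise ValidationError("need at least two components")
        if self.noise_sd < 0 or self.jitter_sd < 0:
            raise ValidationError("noise amplitudes must be >= 0")


def generate_score_table(
    spec: ScoreSpec,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Synthetic score table, per-compound pIC50, and the true weights.

    Each compound's pIC50 equals the weighted component sum (plus noise);
    per-snapshot jitter on the components makes optimal-score selection
    nontrivial while leaving the per-compound base values recoverable.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.component_weights)
    w = np.array([spec.component_weights[c] for c in names])
    base = rng.normal(0.0, 1.0, (spec.n_compounds, len(names)))
    pic50 = spec.intercept + base @ w
    if spec.noise_sd > 0:
        pic50 = pic50 + rng.normal(0.0, spec.noise_sd, spec.n_compounds)
    rows = []
    for ci in range(spec.n_compounds):
        cid = f"S{ci + 1:02d}"
        for si in range(spec.n_snapshots):
            comp = base[ci]
            if spec.jitter_sd > 0:
                comp = comp + rng.normal(0.0, spec.jitter_sd, len(names))
            total = spec.intercept + comp @ w
            row = {
                "derivative_id": cid,
                "replica": 1 + si % spec.n_replicas,
                "time_ns": 40.0 + 0.1 * si,
                "function": spec.function,
                "total": total,
            }
            row.update({c: v for c, v in zip(names, comp)})
            rows.append(row)
    table = pd.DataFrame(rows)
    pic = pd.Series(pic50, index=[f"S{ci + 1:02d}" for ci in range(spec.n_compounds)])
    truth = {
        "component_weights": dict(spec.component_weights),
        "intercept": spec.intercept,
        "noise_sd": spec.noise_sd,
        "jitter_sd": spec.jitter_sd,
        "direction": spec.direction,
        "seed": spec.seed,
    }
    return table, pic, truth
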