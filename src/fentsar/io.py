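"""Readers and writers: PDB structures, multi-model PDB trajectories, the
affinity table, and JSON configuration for residue roles and fragment schemes.

Trajectory input is deliberately text-first: multi-model PDB is the guaranteed
format (binary formats can be converted upstream), which keeps every analysis
reproducible from plain-text fixtures.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .core import (
    ATOM_TABLE_COLUMNS,
    AffinityRecord,
    FragmentScheme,
    ResidueRoleMap,
    Snapshot,
    TrajectoryPool,
    ValidationError,
)

__all__ = [
    "ParseError",
    "ReplicaTrajectory",
    "build_snapshot_pool",
    "load_affinity_table",
    "load_reference_affinities",
    "read_structure",
    "read_trajectory_pdb",
    "save_affinity_table",
    "write_trajectory_pdb",
]


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


WATER_RESIDUE_NAMES = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP", "SPC", "TIP4"})
ION_RESIDUE_NAMES = frozenset(
    {"NA", "CL", "K", "MG", "ZN", "CA", "MN", "FE", "CU", "SOD", "CLA", "POT"}
)
LIPID_RESIDUE_NAMES = frozenset(
    {"POPC", "POPE", "POPS", "POPG", "DPPC", "DOPC", "DMPC", "CHL1", "CHOL"}
)
PROTEIN_RESIDUE_NAMES = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
        "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "CYX", "CYM", "ASH", "GLH",
    }
)


def _categorize(res_name: str, hetero: bool) -> str:
    res_name = res_name.strip().upper()
    if res_name in WATER_RESIDUE_NAMES:
        return "water"
    if res_name in ION_RESIDUE_NAMES:
        return "ion"
    if res_name in LIPID_RESIDUE_NAMES:
        return "lipid"
    if res_name in PROTEIN_RESIDUE_NAMES:
        return "protein"
    if hetero:
        return "ligand"
    return "other"


def _element_symbol(raw: str, atom_name: str) -> str:
    e = raw.strip()
    if not e:
        # fall back on the first alphabetic character of the atom name
        e = next((c for c in atom_name if c.isalpha()), "C")
    return e.capitalize() if len(e) > 1 else e.upper()


def _atoms_frame(array: struc.AtomArray) -> pd.DataFrame:
    names = [n.strip() for n in array.atom_name]
    elements = [
        _element_symbol(e, n) for e, n in zip(array.element, names)
    ]
    categories = [
        _categorize(rn, bool(h)) for rn, h in zip(array.res_name, array.hetero)
    ]
    return pd.DataFrame(
        {
            "name": names,
            "element": elements,
            "residue_number": array.res_id.astype(int),
            "residue_name": [r.strip() for r in array.res_name],
            "chain": [c.strip() for c in array.chain_id],
            "category": categories,
        },
        columns=list(ATOM_TABLE_COLUMNS),
    )


def _locate_malformed_line(path: Path) -> str | None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except (ValueError, IndexError):
                    return f"malformed ATOM/HETATM record at line {lineno}"
    return None


def _has_atom_records(path: Path) -> bool:
    with open(path) as fh:
        return any(line.startswith(("ATOM", "HETATM")) for line in fh)


def _read_pdb_models(path: str | Path) -> struc.AtomArrayStack:
    path = Path(path)
    if not _has_atom_records(path):
        raise ParseError(f"{path}: no atoms")
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:
        detail = _locate_malformed_line(path)
        raise ParseError(
            f"{path}: {detail or f'could not parse PDB ({exc})'}"
        ) from exc
    if stack.array_length() == 0:
        raise ParseError(f"{path}: no atoms")
    return stack


def read_structure(path: str | Path) -> tuple[pd.DataFrame, Snapshot]:
    """Read a single-model PDB into an atom table plus one snapshot.

    Water is recognised by residue name (HOH/WAT/SOL/TIP3...), ligands by the
    HETATM flag; 1-based residue numbers are preserved verbatim.
    """
    stack = _read_pdb_models(path)
    atoms = _atoms_frame(stack[0])
    snap = Snapshot(
        atoms=atoms,
        positions=np.asarray(stack.coord[0], dtype=float),
        time=0.0,
        replica_id=1,
    )
    return atoms, snap


@dataclass
class ReplicaTrajectory:
    """Frames of one production replica, before pooling."""

    atoms: pd.DataFrame
    coords: np.ndarray  # (frames, atoms, 3), Angstrom
    times: np.ndarray  # ns, ascending
    replica_id: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.shape[0] != self.times.shape[0]:
            raise ValidationError("one time stamp per frame required")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("frame times must be strictly increasing")


def read_trajectory_pdb(
    path: str | Path,
    replica_id: int = 1,
    dt_ns: float = 0.01,
    t0_ns: float = 0.0,
) -> ReplicaTrajectory:
    """Read a multi-model PDB as one replica; model *k* gets time
    ``t0_ns + k * dt_ns``."""
    stack = _read_pdb_models(path)
    atoms = _atoms_frame(stack[0])
    n = stack.stack_depth()
    times = t0_ns + dt_ns * np.arange(n)
    return ReplicaTrajectory(
        atoms=atoms,
        coords=np.asarray(stack.coord, dtype=float),
        times=times,
        replica_id=replica_id,
    )


def write_trajectory_pdb(
    atoms: pd.DataFrame, coords: np.ndarray, path: str | Path
) -> None:
    """Write coordinate frames over one atom table as a multi-model PDB."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_atoms = len(atoms)
    template = struc.AtomArray(n_atoms)
    template.coord = coords[0]
    template.atom_name = atoms["name"].to_numpy(dtype="U6")
    template.element = atoms["element"].str.upper().to_numpy(dtype="U2")
    template.res_id = atoms["residue_number"].to_numpy(dtype=int)
    template.res_name = atoms["residue_name"].to_numpy(dtype="U5")
    template.chain_id = atoms["chain"].to_numpy(dtype="U4")
    template.hetero = ~atoms["category"].isin(["protein"]).to_numpy()
    stack = struc.stack([template] * coords.shape[0])
    stack.coord = coords
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def build_snapshot_pool(
    replicas: Sequence[ReplicaTrajectory],
    tail_ns: float = 10.0,
    per_ns: int = 100,
    derivative_id: str = "",
) -> TrajectoryPool:
    """Pool the final ``tail_ns`` of each replica at ``per_ns`` frames per ns.

    The retained window is half-open, ``[t_end - tail_ns, t_end)`` with
    ``t_end`` one frame-interval past the last stamp, and frames are
    subsampled uniformly by index when the source rate exceeds ``per_ns``.
    With the defaults (three replicas, 10 ns tail, 100 frames/ns) a pool
    holds 3000 snapshots.  Deterministic: identical inputs select identical
    frames.
    """
    if not replicas:
        raise ValidationError("at least one replica required")
    n_target = int(round(tail_ns * per_ns))
    if n_target < 1:
        raise ValidationError("tail_ns * per_ns must be >= 1")
    ref_atoms = replicas[0].atoms
    frames, times, labels = [], [], []
    for rep in replicas:
        if len(rep.atoms) != len(ref_atoms) or not np.array_equal(
            rep.atoms["name"].to_numpy(), ref_atoms["name"].to_numpy()
        ):
            raise ValidationError(
                f"replica {rep.replica_id} atom table differs from replica "
                f"{replicas[0].replica_id}"
            )
        t = rep.times
        dt = float(np.median(np.diff(t))) if t.size > 1 else tail_ns / n_target
        t_end = float(t[-1]) + dt
        span = t_end - float(t[0])
        if span + 1e-9 < tail_ns:
            raise ValidationError(
                f"replica {rep.replica_id} spans only {span:.3f} ns, "
                f"shorter than the requested {tail_ns} ns tail"
            )
        window = np.flatnonzero((t >= t_end - tail_ns - 1e-9) & (t < t_end))
        if window.size < n_target:
            raise ValidationError(
                f"replica {rep.replica_id} has {window.size} frames in the "
                f"final {tail_ns} ns but {n_target} are required"
            )
        sel = window[
            np.floor(np.arange(n_target) * window.size / n_target).astype(int)
        ]
        frames.append(rep.coords[sel])
        times.append(t[sel])
        labels.append(np.full(n_target, rep.replica_id, dtype=int))
    return TrajectoryPool(
        atoms=ref_atoms,
        coords=np.concatenate(frames, axis=0),
        times=np.concatenate(times),
        replicas=np.concatenate(labels),
        derivative_id=derivative_id,
    )


# ---------------------------------------------------------------------------
# Affinity tables
# ---------------------------------------------------------------------------

def _parse_affinity_row(row: dict, lineno: int) -> AffinityRecord:
    cid = (row.get("compound_id") or "").strip()
    raw_ic50 = (row.get("ic50_nM") or "").strip()
    raw_sd = (row.get("sd_nM") or "").strip()
    if not cid or not raw_ic50:
        raise ParseError(f"affinity row {lineno}: compound_id and ic50_nM required")
    censored = raw_ic50.startswith(">")
    try:
        ic50 = float(raw_ic50.lstrip(">"))
    except ValueError:
        raise ParseError(
            f"affinity row {lineno}: cannot parse IC50 {raw_ic50!r}"
        ) from None
    sd = None
    if raw_sd not in ("", "-"):
        sd = float(raw_sd)
    chiral = (row.get("chiral") or "0").strip() in ("1", "true", "True")
    return AffinityRecord(
        compound_id=cid,
        ic50=ic50,
        sd=sd,
        censored=censored,
        chiral=chiral,
        name=(row.get("name") or "").strip(),
        ic50_text=raw_ic50,
        sd_text=raw_sd,
    )


def load_affinity_table(path: str | Path) -> list[AffinityRecord]:
    """Load a CSV of compound_id, ic50_nM, sd_nM (plus optional name/chiral).

    ">1000" style entries become censored records whose pIC50 is undefined;
    they are excluded from regressions downstream by default.
    """
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "ic50_nM" not in reader.fieldnames:
            raise ParseError(f"{path}: missing required column ic50_nM")
        for lineno, row in enumerate(reader, start=2):
            records.append(_parse_affinity_row(row, lineno))
    return records


def _format_ic50(rec: AffinityRecord) -> str:
    if rec.ic50_text:
        return rec.ic50_text
    if rec.censored:
        # conventional ">1000.0" rendering for a censored ceiling
        return f">{rec.ic50:.1f}"
    return f"{rec.ic50:g}"


def _format_sd(rec: AffinityRecord) -> str:
    if rec.sd_text:
        return rec.sd_text
    return "" if rec.sd is None else f"{rec.sd:g}"


def save_affinity_table(records: Sequence[AffinityRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["compound_id", "name", "ic50_nM", "sd_nM", "chiral"])
        for rec in records:
            writer.writerow(
                [rec.compound_id, rec.name, _format_ic50(rec), _format_sd(rec),
                 int(rec.chiral)]
            )


def load_reference_affinities() -> list[AffinityRecord]:
    """The packaged 21-compound radioligand-displacement table (IC50 in nM)."""
    with resources.as_file(
        resources.files("fentsar.data") / "mu_or_affinity.csv"
    ) as p:
        return load_affinity_table(p)


def affinity_frame(records: Sequence[AffinityRecord]) -> pd.DataFrame:
    """Tidy view of affinity records with derived pIC50 (NaN when censored)."""
    return pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "name": [r.name for r in records],
            "ic50_nM": [r.ic50 for r in records],
            "sd_nM": [math.nan if r.sd is None else r.sd for r in records],
            "censored": [r.censored for r in records],
            "chiral": [r.chiral for r in records],
            "pic50": [r.pic50 for r in records],
        }
    )


# ---------------------------------------------------------------------------
# JSON configuration
# ---------------------------------------------------------------------------

def load_role_map(path: str | Path) -> ResidueRoleMap:
    with open(path) as fh:
        return ResidueRoleMap.from_json_dict(json.load(fh))


def save_role_map(role_map: ResidueRoleMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(role_map.to_json_dict(), fh, indent=1)


def load_fragment_scheme(path: str | Path) -> FragmentScheme:
    with open(path) as fh:
        return FragmentScheme.from_json_dict(json.load(fh))


def save_fragment_scheme(scheme: FragmentScheme, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(scheme.to_json_dict(), fh, indent=1)
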