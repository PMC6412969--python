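"""Domain types shared by all analysis stages.

The central container is :class:`TrajectoryPool`: a fixed atom table plus a
stack of coordinate frames drawn from the tail of several replica simulations
of one receptor-ligand complex.  All descriptor, contact, volume and scoring
stages consume pools; nothing downstream re-reads trajectory files.

Residue *roles* decouple the analysis from any particular construct numbering:
the labels used throughout opioid-receptor work (D147, Y326, W293, ...) are
bound to actual residue numbers through a :class:`ResidueRoleMap`, so the same
code runs against murine, rat or human numbering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ATOM_CATEGORIES",
    "AffinityRecord",
    "AtomRecord",
    "FRAGMENT_LABELS",
    "FragmentScheme",
    "ResidueRoleMap",
    "Snapshot",
    "TrajectoryPool",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


ATOM_CATEGORIES = frozenset(
    {"protein", "ligand", "water", "ion", "lipid", "other"}
)

#: Element symbols accepted in atom tables (covers proteins, common ligands,
#: solvent, ions and membrane lipids; extend here if an input needs more).
KNOWN_ELEMENTS = frozenset(
    {
        "H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "B",
        "Na", "K", "Mg", "Ca", "Zn", "Fe", "Mn", "Cu", "Se",
    }
)

FRAGMENT_LABELS = (
    "piperidine",
    "n_chain",
    "anilide_aromatic",
    "propanamide",
    "axial_4",
)

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

#: Binding-site and helix roles referenced by the analyses, with the default
#: (murine-construct) residue numbers.  Every number can be overridden.
DEFAULT_ROLES: dict[str, int] = {
    "D147": 147, "Y148": 148, "W133": 133, "M151": 151, "W293": 293,
    "H297": 297, "W318": 318, "H319": 319, "Y326": 326, "Y336": 336,
    "D114": 114, "C217": 217, "I144": 144, "V143": 143, "I296": 296,
    "I322": 322, "L219": 219, "L232": 232, "T218": 218, "S55": 55,
    "V300": 300, "Q124": 124,
}

#: Transmembrane helix backbone ranges (inclusive residue intervals).
DEFAULT_HELIX_RANGES: dict[str, tuple[int, int]] = {
    "H1": (72, 92),
    "H2": (104, 128),
    "H3": (139, 169),
    "H4": (185, 204),
    "H5": (227, 260),
    "H6": (275, 304),
    "H7": (314, 338),
}

ATOM_TABLE_COLUMNS = (
    "name",
    "element",
    "residue_number",
    "residue_name",
    "chain",
    "category",
)


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared atom table."""

    index: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain: str
    category: str
    position: np.ndarray

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValidationError(f"negative atom index {self.index}")
        if self.element not in KNOWN_ELEMENTS:
            raise ValidationError(f"unknown element symbol {self.element!r}")
        if self.category not in ATOM_CATEGORIES:
            raise ValidationError(f"unknown atom category {self.category!r}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValidationError("atom position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class Snapshot:
    """One trajectory frame: positions for a shared atom table."""

    atoms: pd.DataFrame
    positions: np.ndarray
    time: float
    replica_id: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.atoms), 3):
            raise ValidationError(
                f"snapshot has {self.positions.shape[0]} positions for "
                f"{len(self.atoms)} atoms"
            )
        if self.time < 0:
            raise ValidationError("snapshot time must be >= 0 ns")
        if self.replica_id < 1:
            raise ValidationError("replica_id must be >= 1")


@dataclass
class TrajectoryPool:
    """Ordered snapshot collection over one atom table.

    ``coords`` has shape ``(n_frames, n_atoms, 3)`` in Angstrom, ``times`` is
    in ns and ``replicas`` holds the 1-based replica label of every frame.
    Frames are kept sorted by ``(replica, time)``.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    times: np.ndarray
    replicas: np.ndarray
    derivative_id: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in ATOM_TABLE_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValidationError(f"atom table lacks columns {missing}")
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.replicas = np.asarray(self.replicas, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValidationError(
                "coordinate frames do not match the shared atom table length"
            )
        n = self.coords.shape[0]
        if self.times.shape != (n,) or self.replicas.shape != (n,):
            raise ValidationError("times/replicas must have one entry per frame")
        if n and self.replicas.min() < 1:
            raise ValidationError("replica labels must be >= 1")
        order = np.lexsort((self.times, self.replicas))
        if not np.array_equal(order, np.arange(n)):
            self.coords = self.coords[order]
            self.times = self.times[order]
            self.replicas = self.replicas[order]

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def replica_ids(self) -> np.ndarray:
        return np.unique(self.replicas)

    def snapshot(self, i: int) -> Snapshot:
        return Snapshot(
            atoms=self.atoms,
            positions=self.coords[i],
            time=float(self.times[i]),
            replica_id=int(self.replicas[i]),
        )

    def iter_snapshots(self) -> Iterator[Snapshot]:
        for i in range(self.n_frames):
            yield self.snapshot(i)

    def atom_record(self, i: int) -> AtomRecord:
        row = self.atoms.iloc[i]
        return AtomRecord(
            index=int(i),
            name=row["name"],
            element=row["element"],
            residue_number=int(row["residue_number"]),
            residue_name=row["residue_name"],
            chain=row["chain"],
            category=row["category"],
            position=self.coords[0, i] if self.n_frames else np.zeros(3),
        )

    # -- selections -----------------------------------------------------
    def residue_atom_indices(
        self, residue_number: int, names: Sequence[str] | None = None
    ) -> np.ndarray:
        mask = self.atoms["residue_number"].to_numpy() == residue_number
        mask &= self.atoms["category"].to_numpy() == "protein"
        if names is not None:
            mask &= np.isin(self.atoms["name"].to_numpy(), list(names))
        return np.flatnonzero(mask)

    def atom_index(self, residue_number: int, atom_name: str) -> int:
        idx = self.residue_atom_indices(residue_number, [atom_name])
        if idx.size == 0:
            raise ValidationError(
                f"no atom {atom_name!r} in residue {residue_number}"
            )
        return int(idx[0])

    def backbone_indices(
        self, residue_range: tuple[int, int] | None = None
    ) -> np.ndarray:
        """Protein backbone (N, CA, C, O) atom indices, optionally limited to
        an inclusive residue-number interval."""
        names = self.atoms["name"].to_numpy()
        mask = np.isin(names, ["N", "CA", "C", "O"])
        mask &= self.atoms["category"].to_numpy() == "protein"
        if residue_range is not None:
            lo, hi = residue_range
            resnum = self.atoms["residue_number"].to_numpy()
            mask &= (resnum >= lo) & (resnum <= hi)
        return np.flatnonzero(mask)

    def water_molecules(self) -> list[np.ndarray]:
        """Atom-index groups, one per water molecule."""
        water = self.atoms.index[self.atoms["category"] == "water"]
        if len(water) == 0:
            return []
        sub = self.atoms.loc[water]
        groups = sub.groupby(["chain", "residue_number"], sort=True).groups
        return [np.asarray(v, dtype=int) for v in groups.values()]


@dataclass
class ResidueRoleMap:
    """Binds role labels (D147, Y326, ...) and helix names to residue numbers."""

    roles: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ROLES))
    helix_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_HELIX_RANGES)
    )

    def __post_init__(self) -> None:
        ivals = sorted(self.helix_ranges.values())
        for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
            if a1 < a0 or b1 < b0:
                raise ValidationError("helix interval reversed")
            if b0 <= a1:
                raise ValidationError("helix intervals overlap")

    def residue_number(self, role: str) -> int:
        try:
            return self.roles[role]
        except KeyError:
            raise ValidationError(f"unknown residue role {role!r}") from None

    def residue_name(self, role: str) -> str:
        """Three-letter residue name implied by the role label."""
        one = role[0].upper()
        try:
            return _ONE_TO_THREE[one]
        except KeyError:
            raise ValidationError(
                f"role {role!r} does not start with a one-letter residue code"
            ) from None

    def helix_range(self, helix: str) -> tuple[int, int]:
        try:
            return self.helix_ranges[helix]
        except KeyError:
            raise ValidationError(f"unknown helix {helix!r}") from None

    def to_json_dict(self) -> dict:
        return {
            "roles": dict(self.roles),
            "helix_ranges": {k: list(v) for k, v in self.helix_ranges.items()},
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "ResidueRoleMap":
        return cls(
            roles={k: int(v) for k, v in d["roles"].items()},
            helix_ranges={
                k: (int(v[0]), int(v[1])) for k, v in d["helix_ranges"].items()
            },
        )


@dataclass
class FragmentScheme:
    """Partition of the ligand's atoms into pharmacophoric fragments.

    ``fragments`` maps each fragment label to global atom-table indices; the
    labels partition the ligand's heavy atoms (``axial_4`` may be empty, e.g.
    for the parent compound which carries no 4-axial substituent).  Hydrogens
    may be included with their heavy-atom's fragment.  ``bonds`` (optional
    ligand connectivity) is used to decide which carbons/sulfurs count as
    apolar for hydrophobic-contact typing.
    """

    fragments: dict[str, list[int]]
    protonable_nitrogen: int
    aromatic_rings: list[list[int]] = field(default_factory=list)
    bonds: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        unknown = set(self.fragments) - set(FRAGMENT_LABELS)
        if unknown:
            raise ValidationError(f"unknown fragment labels {sorted(unknown)}")
        seen: set[int] = set()
        for label, idx in self.fragments.items():
            dup = seen.intersection(idx)
            if dup:
                raise ValidationError(
                    f"atoms {sorted(dup)} assigned to more than one fragment"
                )
            seen.update(idx)
        if self.protonable_nitrogen not in set(
            self.fragments.get("piperidine", [])
        ):
            raise ValidationError(
                "protonable_nitrogen must belong to the piperidine fragment"
            )

    def fragment_atoms(self, label: str) -> np.ndarray:
        if label not in FRAGMENT_LABELS:
            raise ValidationError(f"unknown fragment label {label!r}")
        return np.asarray(self.fragments.get(label, []), dtype=int)

    def all_atoms(self) -> np.ndarray:
        out: list[int] = []
        for label in FRAGMENT_LABELS:
            out.extend(self.fragments.get(label, []))
        return np.asarray(sorted(out), dtype=int)

    def validate_against(self, atoms: pd.DataFrame) -> None:
        """Check the scheme partitions the ligand's heavy atoms of ``atoms``."""
        ligand = atoms.index[
            (atoms["category"] == "ligand") & (atoms["element"] != "H")
        ]
        covered = set(self.all_atoms())
        heavy = set(int(i) for i in ligand)
        missing = heavy - covered
        if missing:
            raise ValidationError(
                f"ligand heavy atoms not covered by the scheme: {sorted(missing)}"
            )

    def neighbours(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {}
        for a, b in self.bonds or []:
            adj.setdefault(int(a), set()).add(int(b))
            adj.setdefault(int(b), set()).add(int(a))
        return adj

    def to_json_dict(self) -> dict:
        return {
            "fragments": {k: list(map(int, v)) for k, v in self.fragments.items()},
            "protonable_nitrogen": int(self.protonable_nitrogen),
            "aromatic_rings": [list(map(int, r)) for r in self.aromatic_rings],
            "bonds": None
            if self.bonds is None
            else [[int(a), int(b)] for a, b in self.bonds],
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "FragmentScheme":
        return cls(
            fragments={k: [int(i) for i in v] for k, v in d["fragments"].items()},
            protonable_nitrogen=int(d["protonable_nitrogen"]),
            aromatic_rings=[[int(i) for i in r] for r in d.get("aromatic_rings", [])],
            bonds=None
            if d.get("bonds") is None
            else [(int(a), int(b)) for a, b in d["bonds"]],
        )


@dataclass(frozen=True)
class AffinityRecord:
    """One row of the competitive radioligand displacement table.

    ``ic50`` is in nM.  A censored record (no displacement detected up to the
    assay ceiling, reported as ">1000") carries the ceiling in ``ic50`` and
    has no defined pIC50.
    """

    compound_id: str
    ic50: float
    sd: float | None = None
    censored: bool = False
    chiral: bool = False
    name: str = ""
    #: verbatim source text for IC50/SD, kept so tables round-trip exactly
    ic50_text: str = ""
    sd_text: str = ""

    def __post_init__(self) -> None:
        if not self.ic50 > 0:
            raise ValidationError(
                f"{self.compound_id}: IC50 must be positive, got {self.ic50}"
            )
        if self.sd is not None and self.sd < 0:
            raise ValidationError(f"{self.compound_id}: negative SD")

    @property
    def pic50(self) -> float:
        """-log10(IC50 in molar); undefined (NaN) for censored records."""
        if self.censored:
            return math.nan
        return 9.0 - math.log10(self.ic50)
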