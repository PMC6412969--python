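"""Small vector-geometry kernels: signed dihedrals, internal-coordinate atom
placement and least-squares superposition.

All functions broadcast over leading axes, so the synthetic generator can
place one atom across every frame of a pool in a single call.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["dihedral_deg", "place_atom", "superpose", "wrap_deg"]


def wrap_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles in degrees onto (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    out = -np.remainder(-a + 180.0, 360.0) + 180.0
    return out if out.ndim else float(out)


def _norm(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def dihedral_deg(a, b, c, d) -> np.ndarray | float:
    """Signed dihedral angle A-B-C-D in degrees, right-hand convention,
    in (-180, 180]."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, _norm(b2))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return wrap_deg(ang)


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral: np.ndarray | float):
    """Place atom D from reference positions A, B, C such that |C-D| = bond,
    the B-C-D angle equals ``angle_deg`` and the A-B-C-D dihedral equals
    ``dihedral`` (degrees).  Standard natural-extension (NeRF) construction.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    phi = np.radians(np.asarray(dihedral, dtype=float))
    theta = np.radians(angle_deg)
    bc = _norm(c - b)
    ab = b - a
    n = _norm(np.cross(ab, bc))
    m = np.cross(n, bc)
    d_local = np.stack(
        [
            -bond * np.cos(theta) * np.ones_like(phi),
            bond * np.sin(theta) * np.cos(phi),
            -bond * np.sin(theta) * np.sin(phi),
        ],
        axis=-1,
    )
    frame = np.stack([bc, m, n], axis=-1)  # columns are the local basis
    return c + np.einsum("...ij,...j->...i", frame, d_local)


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the transformed copy of ``mobile`` (rotation + translation only;
    proper rotation enforced).  Both arrays have shape (n_atoms, 3).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - cr, mobile - cm)
    return rot.apply(mobile - cm) + cr


def superposition_transform(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[Rotation, np.ndarray, np.ndarray]:
    """Rotation and centroids of the fit, for applying the same rigid motion
    to atoms outside the fitted selection."""
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - cr, mobile - cm)
    return rot, cm, cr
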