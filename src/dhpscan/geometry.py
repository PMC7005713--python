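"""Pure-geometry kernel: torsions, rotamer bins, contacts, Kabsch superposition.

Everything here is seedless and side-effect free.  Angles are degrees in
(-180, +180], coordinates Cartesian angstroms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Chi1Angle",
    "RotamerPartition",
    "DEFAULT_PARTITION",
    "Superposition",
    "ContactPair",
    "dihedral",
    "chi1",
    "classify_rotamer",
    "kabsch_superpose",
    "contact_search",
]

CHI1_ATOMS = ("N", "CA", "CB", "CG")

# Heavy-atom donor-acceptor distance typical for a hydrogen bond.
DEFAULT_CONTACT_CUTOFF = 3.6


class DegenerateGeometryError(ValueError):
    """Raised when input points are collinear/degenerate for the operation."""


@dataclass(frozen=True)
class Chi1Angle:
    """A chi1 torsion measurement for one altloc-consistent atom set."""

    value: float  # degrees in (-180, +180]
    atoms_used: tuple[str, str, str, str] = CHI1_ATOMS

    def __post_init__(self) -> None:
        if not (-180.0 < self.value <= 180.0):
            raise ValueError(f"chi1 out of (-180, 180]: {self.value}")


@dataclass(frozen=True)
class RotamerPartition:
    """Half-open chi1 bins for gauche-/gauche+/trans classification.

    The default follows the IUPAC sign convention with canonical rotamers at
    -60 (gauche-, "m"), +60 (gauche+, "p") and 180 (trans, "t"): gauche- on
    [-120, 0), gauche+ on [0, +120), trans on the remainder of the circle.
    Lower bin edges are inclusive, so exactly -120 is gauche- and exactly 0
    is gauche+.
    """

    gauche_minus: tuple[float, float] = (-120.0, 0.0)
    gauche_plus: tuple[float, float] = (0.0, 120.0)

    def classify(self, angle: float) -> str:
        if not (-180.0 < angle <= 180.0):
            raise ValueError(f"chi1 out of (-180, 180]: {angle}")
        lo, hi = self.gauche_minus
        if lo <= angle < hi:
            return "gauche-"
        lo, hi = self.gauche_plus
        if lo <= angle < hi:
            return "gauche+"
        return "trans"

    def mirrored(self) -> "RotamerPartition":
        """Partition under the opposite sign convention (gauche- near +60)."""
        return RotamerPartition(
            gauche_minus=(0.0, 120.0), gauche_plus=(-120.0, 0.0)
        )


DEFAULT_PARTITION = RotamerPartition()

ROTAMER_LABELS = ("gauche-", "gauche+", "trans")


@dataclass(frozen=True)
class Superposition:
    """Optimal least-squares rigid alignment of paired point sets.

    ``rotation @ x + translation`` maps mobile points onto the reference.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")
        if self.n_pairs < 3:
            raise ValueError("need at least 3 pairs")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class ContactPair:
    """One donor-partner heavy-atom contact within a cutoff."""

    donor_name: str
    partner_name: str
    distance: float
    donor_index: int = -1
    partner_index: int = -1

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("contact distance must be > 0")


def _as_vec(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite coordinates")
    return v


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention.

    cis (eclipsed) is 0 deg; looking from p2 towards p3, a clockwise turn of
    the far bond is positive.  Result lies in (-180, +180].

    Raises
    ------
    DegenerateGeometryError
        If three consecutive points are collinear (torsion undefined).
    """
    p1, p2, p3, p4 = (_as_vec(p) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n == 0 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("collinear or coincident points: torsion undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / b2n)
    angle = np.degrees(np.arctan2(y, x))
    if angle <= -180.0:  # map -180 -> +180 so range is (-180, 180]
        angle += 360.0
    return float(angle)


def chi1(atom_coords: dict) -> Chi1Angle:
    """chi1 torsion (N-CA-CB-CG) from a name->coordinate mapping.

    The mapping must come from one altloc-consistent atom set; see
    :meth:`dhpscan.structures.ResidueView.altloc_groups`.
    """
    missing = [name for name in CHI1_ATOMS if name not in atom_coords]
    if missing:
        raise KeyError(f"chi1 atoms missing: {', '.join(missing)}")
    return Chi1Angle(dihedral(*(atom_coords[name] for name in CHI1_ATOMS)))


def classify_rotamer(chi1_deg: float, partition: RotamerPartition = DEFAULT_PARTITION) -> str:
    """Classify a chi1 angle as 'gauche-', 'gauche+' or 'trans'."""
    return partition.classify(float(chi1_deg))


def kabsch_superpose(coords_ref: Sequence, coords_mobile: Sequence) -> Superposition:
    """Least-squares optimal rigid superposition of mobile onto reference.

    Standard Kabsch solution via SVD of the covariance matrix, with the
    reflection corrected so the returned rotation is proper (det +1).

    Parameters
    ----------
    coords_ref, coords_mobile:
        Paired (n, 3) arrays, n >= 3.  Pairing is positional.
    """
    A = np.asarray(coords_ref, dtype=float)
    B = np.asarray(coords_mobile, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"paired (n,3) arrays required, got {A.shape} and {B.shape}")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12:  # rank < 2: rotation about the cloud not determined
        raise DegenerateGeometryError("rank-deficient covariance: degenerate point cloud")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    diff = (B0 @ R.T) - A0
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_pairs=n)


def contact_search(
    atoms_a: Iterable[tuple[str, Sequence[float]]],
    atoms_b: Iterable[tuple[str, Sequence[float]]],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list[ContactPair]:
    """All cross pairs (a, b) with distance <= cutoff, sorted by distance.

    ``atoms_a``/``atoms_b`` are iterables of (name, xyz).  The search is a
    dense all-pairs distance computation; inputs here are residue-scale
    (tens of atoms), so no spatial index is needed.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    la = list(atoms_a)
    lb = list(atoms_b)
    if not la or not lb:
        return []
    xa = np.asarray([_as_vec(c) for _, c in la])
    xb = np.asarray([_as_vec(c) for _, c in lb])
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
    pairs = [
        ContactPair(
            donor_name=la[i][0],
            partner_name=lb[j][0],
            distance=float(d[i, j]),
            donor_index=i,
            partner_index=j,
        )
        for i, j in zip(*np.nonzero((d <= cutoff) & (d > 0)))
    ]
    pairs.sort(key=lambda p: (p.distance, p.donor_index, p.partner_index))
    return pairs
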