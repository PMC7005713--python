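"""Synthetic inputs for the pipeline: idealized His structures and decay curves.

Structures are built from internal coordinates (bond length, bond angle,
torsion — the NeRF construction), so the target chi1 is exact by
construction rather than approximated by rotating a template.  The imidazole
ring beyond CG is completed with ideal planar geometry at a fixed chi2 so
that Nd1/Ne2 exist for contact tests; chi2 is not a studied variable.

Decay curves are exact exponentials with multiplicative lognormal noise:
gel-band signals are positive and their error scales with band intensity.
All randomness flows through an explicit numpy seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from dhpscan.kinetics import DEFAULT_TIME_GRID, TimeCourse
from dhpscan.structures import AtomRecord, ResidueView, write_pdb_fixture

__all__ = [
    "ResidueBuildSpec",
    "SimulatedStructureSpec",
    "DecaySimSpec",
    "place_atom",
    "build_his_residue",
    "build_structure",
    "build_survey_fixtures",
    "simulate_decay",
    "CANONICAL_CHI1",
]

# Canonical chi1 rotamer centres (IUPAC sign convention).
CANONICAL_CHI1 = {"gauche-": -60.0, "gauche+": 60.0, "trans": 180.0}

# Common His chi2; only needed so the ring exists for contact geometry.
DEFAULT_CHI2 = -75.0


@dataclass(frozen=True)
class ResidueBuildSpec:
    """Ideal-geometry parameters for one His residue build."""

    chi1: float
    chi2: float = DEFAULT_CHI2
    bond_n_ca: float = 1.46
    bond_ca_cb: float = 1.53
    bond_cb_cg: float = 1.50
    angle_n_ca_cb: float = 110.5
    angle_ca_cb_cg: float = 113.8

    def __post_init__(self) -> None:
        for name in ("bond_n_ca", "bond_ca_cb", "bond_cb_cg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("angle_n_ca_cb", "angle_ca_cb_cg"):
            if not (0.0 < getattr(self, name) < 180.0):
                raise ValueError(f"{name} must be in (0, 180)")


@dataclass(frozen=True)
class SimulatedStructureSpec:
    """A multi-chain fixture: one target His per chain at a prescribed chi1.

    ``chain_chi1`` holds, per chain, one or more chi1 values (several values
    make alternate conformers of that subunit).  Rotamer labels may be given
    instead of angles and resolve to the canonical centres.
    """

    chain_chi1: tuple[tuple[float, ...], ...]
    crystallization_ph: float = 7.0
    his_residue: int = 260
    sulfate_distance: Optional[float] = None  # A from Ne2 of first chain, first conformer
    chain_spacing: float = 25.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.crystallization_ph <= 14.0):
            raise ValueError("declared pH must be in [0, 14]")
        if not self.chain_chi1:
            raise ValueError("at least one chain required")

    @classmethod
    def from_labels(cls, labels: Sequence[Sequence[str] | str], **kwargs) -> "SimulatedStructureSpec":
        chains = []
        for sub in labels:
            if isinstance(sub, str):
                sub = [sub]
            chains.append(tuple(CANONICAL_CHI1[lab] for lab in sub))
        return cls(chain_chi1=tuple(chains), **kwargs)


@dataclass(frozen=True)
class DecaySimSpec:
    """Exponential-decay simulation: half-life (min), grid, noise, replicates."""

    half_life: float
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID
    sigma: float = 0.05
    replicates: int = 1
    seed: int = 0
    condition: str = ""

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError("half-life must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom D from reference chain A-B-C by internal coordinates.

    |C-D| = bond, angle(B,C,D) = angle_deg and torsion(A,B,C,D) = torsion_deg
    under the IUPAC sign convention used by :func:`dhpscan.geometry.dihedral`.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm_n = np.linalg.norm(n)
    if norm_n < 1e-10:
        raise ValueError("degenerate reference frame (collinear A, B, C)")
    n /= norm_n
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _his_atom_positions(spec: ResidueBuildSpec) -> dict[str, np.ndarray]:
    theta = math.radians(spec.angle_n_ca_cb)
    n = np.zeros(3)
    ca = np.array([spec.bond_n_ca, 0.0, 0.0])
    cb = ca + spec.bond_ca_cb * np.array([-math.cos(theta), math.sin(theta), 0.0])
    cg = place_atom(n, ca, cb, spec.bond_cb_cg, spec.angle_ca_cb_cg, spec.chi1)
    pos = {"N": n, "CA": ca, "CB": cb, "CG": cg}
    # backbone carbonyl, for a more residue-like fixture
    pos["C"] = place_atom(cb, n, ca, 1.52, 111.0, -120.0)
    pos["O"] = place_atom(n, ca, pos["C"], 1.23, 120.5, 180.0)
    # planar imidazole at fixed chi2
    pos["ND1"] = place_atom(ca, cb, cg, 1.38, 122.7, spec.chi2)
    cd2_torsion = spec.chi2 + 180.0
    if cd2_torsion > 180.0:
        cd2_torsion -= 360.0
    pos["CD2"] = place_atom(ca, cb, cg, 1.36, 131.0, cd2_torsion)
    pos["CE1"] = place_atom(cb, cg, pos["ND1"], 1.32, 105.6, 180.0)
    pos["NE2"] = place_atom(cg, pos["ND1"], pos["CE1"], 1.32, 111.7, 0.0)
    return pos


_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C",
            "ND1": "N", "CD2": "C", "CE1": "C", "NE2": "N"}

SIDECHAIN_ATOMS = ("CG", "ND1", "CD2", "CE1", "NE2")


def build_his_residue(
    spec: ResidueBuildSpec,
    chain_id: str = "A",
    residue_number: int = 260,
    altloc: str = "",
    occupancy: float = 1.0,
    offset: Sequence[float] = (0.0, 0.0, 0.0),
) -> ResidueView:
    """Build one ideal-geometry His as a ResidueView at the requested chi1."""
    pos = _his_atom_positions(spec)
    off = np.asarray(offset, dtype=float)
    atoms = [
        AtomRecord(
            atom_name=name,
            element=_ELEMENT[name],
            coords=tuple(pos[name] + off),
            altloc=altloc if name in SIDECHAIN_ATOMS else "",
            occupancy=occupancy if name in SIDECHAIN_ATOMS else 1.0,
            chain_id=chain_id,
            residue_number=residue_number,
            residue_name="HIS",
        )
        for name in ("N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2")
    ]
    return ResidueView(
        chain_id=chain_id, residue_number=residue_number, residue_name="HIS", atoms=atoms
    )


def _sulfate_atoms(ne2: np.ndarray, ce1: np.ndarray, cd2: np.ndarray, distance: float,
                  chain_id: str = "X", residue_number: int = 501) -> list[AtomRecord]:
    # Outward lone-pair direction of Ne2, in the ring plane.
    u = (ne2 - ce1) / np.linalg.norm(ne2 - ce1) + (ne2 - cd2) / np.linalg.norm(ne2 - cd2)
    u /= np.linalg.norm(u)
    o1 = ne2 + distance * u
    s = ne2 + (distance + 1.47) * u
    # remaining oxygens tetrahedral about S, all farther from Ne2 than O1
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    tet = math.radians(109.47)
    others = [
        s + 1.47 * (
            math.cos(tet) * (-u)
            + math.sin(tet) * (math.cos(phi) * e1 + math.sin(phi) * e2)
        )
        for phi in (0.0, 2 * math.pi / 3, 4 * math.pi / 3)
    ]
    coords = {"S": s, "O1": o1, "O2": others[0], "O3": others[1], "O4": others[2]}
    return [
        AtomRecord(
            atom_name=name,
            element=name[0],
            coords=tuple(xyz),
            chain_id=chain_id,
            residue_number=residue_number,
            residue_name="SO4",
        )
        for name, xyz in coords.items()
    ]


def build_structure(spec: SimulatedStructureSpec, path: str | Path) -> Path:
    """Write a multi-chain PDB fixture realizing a SimulatedStructureSpec.

    One His per chain at the prescribed chi1 (several values per chain become
    altloc conformers at equal occupancy), REMARK 280 carrying the declared
    pH, and optionally a sulfate whose nearest oxygen sits at the prescribed
    distance from the first chain's Ne2.
    """
    atoms: list[AtomRecord] = []
    first_ring: Optional[dict[str, np.ndarray]] = None
    for i, chis in enumerate(spec.chain_chi1):
        chain_id = chr(ord("A") + i)
        # non-collinear chain placement so Calpha sets of multi-chain
        # fixtures are usable for superposition
        offset = (
            spec.chain_spacing * i,
            spec.chain_spacing * ((i * i) % 5) * 0.6,
            spec.chain_spacing * ((i * 3) % 4) * 0.4,
        )
        multi = len(chis) > 1
        for j, chi in enumerate(chis):
            altloc = chr(ord("A") + j) if multi else ""
            occ = round(1.0 / len(chis), 2) if multi else 1.0
            res = build_his_residue(
                ResidueBuildSpec(chi1=chi),
                chain_id=chain_id,
                residue_number=spec.his_residue,
                altloc=altloc,
                occupancy=occ,
                offset=offset,
            )
            if multi and j > 0:
                # backbone already emitted with the first conformer
                res_atoms = [a for a in res.atoms if a.altloc]
            else:
                res_atoms = res.atoms
            atoms.extend(res_atoms)
            if first_ring is None:
                first_ring = {a.atom_name: a.xyz for a in res.atoms}
    if spec.sulfate_distance is not None:
        assert first_ring is not None
        atoms.extend(
            _sulfate_atoms(
                first_ring["NE2"], first_ring["CE1"], first_ring["CD2"],
                spec.sulfate_distance,
            )
        )
    remark = f"CRYSTALLIZATION CONDITIONS: SYNTHETIC FIXTURE, PH {spec.crystallization_ph:.2f}"
    return write_pdb_fixture(atoms, path, remarks=[remark])


def build_survey_fixtures(
    manifest, out_dir: str | Path, seed: int = 0, jitter: float = 20.0
) -> tuple[dict[str, Path], dict[str, dict]]:
    """Emit one fixture per manifest entry reproducing its label/pH profile.

    chi1 values are drawn uniformly within +/- ``jitter`` degrees of the
    canonical rotamer centre (staying inside the label's bin), so coordinate-
    mode classification must recover the manifest labels exactly.  Returns
    the written paths and the selector map to use with them.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    selectors: dict[str, dict] = {}
    for entry in manifest:
        chains = []
        for labels in entry.subunit_labels:
            chis = []
            for label in labels:
                centre = CANONICAL_CHI1[label]
                chi = centre + rng.uniform(-jitter, jitter)
                if chi > 180.0:
                    chi -= 360.0
                chis.append(chi)
            chains.append(tuple(chis))
        spec = SimulatedStructureSpec(
            chain_chi1=tuple(chains),
            crystallization_ph=entry.ph_value if entry.ph_value is not None else 7.0,
            his_residue=260,
        )
        paths[entry.pdb_id] = build_structure(spec, out_dir / f"{entry.pdb_id}.pdb")
        selectors[entry.protein] = {"his_residue": 260}
    return paths, selectors


def simulate_decay(spec: DecaySimSpec) -> list[TimeCourse]:
    """Noisy exponential decays: 100*2^(-t/t_half)*exp(eps), eps ~ N(0, sigma^2)."""
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.time_grid, dtype=float)
    clean = 100.0 * np.exp(-math.log(2.0) * t / spec.half_life)
    courses = []
    for i in range(spec.replicates):
        eps = rng.normal(0.0, spec.sigma, size=t.size) if spec.sigma > 0 else np.zeros(t.size)
        courses.append(
            TimeCourse.from_arrays(
                t, clean * np.exp(eps),
                condition=spec.condition or f"rep{i + 1}",
            )
        )
    return courses
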