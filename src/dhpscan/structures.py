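"""Coordinate-file I/O and the light domain model used by the rotamer survey.

Parsing is delegated to gemmi; this module flattens its hierarchy into
altloc-aware residue views keyed by author numbering, extracts the
crystallization pH from the header, and writes the minimal single-character-
chain PDB fixtures used in tests and by the synthetic generator.

Crystallization pH is taken from REMARK 280 free text (PDB) or the
``_exptl_crystal_grow`` category (mmCIF).  A missing or unparseable pH is
reported as ``None`` — never guessed — and a stated range (e.g. 7.6-8.6)
becomes its midpoint with the range recorded alongside the mother liquor.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueView",
    "CrystalMetadata",
    "StructureModel",
    "read_structure",
    "extract_crystal_pH",
    "select_residue",
    "write_pdb_fixture",
    "StructureParseError",
    "ResidueNotFoundError",
]

logger = logging.getLogger(__name__)

ANION_RESIDUES = ("SO4", "GOL", "PO4")
WATER_RESIDUES = ("HOH", "WAT")


class StructureParseError(ValueError):
    """A coordinate file could not be read into the domain model."""


class ResidueNotFoundError(KeyError):
    """A residue selector did not resolve in the structure."""


@dataclass(frozen=True)
class AtomRecord:
    atom_name: str
    element: str
    coords: tuple[float, float, float]
    altloc: str = ""
    occupancy: float = 1.0
    chain_id: str = "A"
    residue_number: int = 1
    insertion_code: str = ""
    residue_name: str = "UNK"
    model_number: int = 1

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        if not all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy out of [0,1]: {self.occupancy}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass
class ResidueView:
    """All atoms of one residue (one chain/number/insertion), altloc-aware."""

    chain_id: str
    residue_number: int
    residue_name: str
    insertion_code: str = ""
    atoms: list[AtomRecord] = field(default_factory=list)

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    def altloc_groups(self) -> dict[str, dict[str, AtomRecord]]:
        """Atom sets keyed by altloc label.

        Atoms with a blank altloc are shared by every group; an explicit
        altloc ('A', 'B', ...) overrides the shared atom of the same name.
        A residue with no explicit altlocs yields the single group ``""``.
        """
        shared = {a.atom_name: a for a in self.atoms if not a.altloc}
        labels = sorted({a.altloc for a in self.atoms if a.altloc})
        if not labels:
            return {"": shared}
        groups: dict[str, dict[str, AtomRecord]] = {}
        for label in labels:
            group = dict(shared)
            group.update({a.atom_name: a for a in self.atoms if a.altloc == label})
            groups[label] = group
        return groups

    def group_occupancy(self, label: str) -> float:
        """Minimum occupancy over the group's explicitly-altloc'd atoms.

        For the blank group (no alternate conformers) the minimum over all
        atoms is returned.
        """
        own = [a.occupancy for a in self.atoms if a.altloc == label]
        if own:
            return min(own)
        return min((a.occupancy for a in self.atoms), default=0.0)

    @property
    def side_chain_complete(self) -> bool:
        """True if N, CA, CB, CG are all present in at least one altloc group."""
        return any(
            all(name in group for name in ("N", "CA", "CB", "CG"))
            for group in self.altloc_groups().values()
        )


@dataclass
class CrystalMetadata:
    pdb_id: str = ""
    crystallization_pH: Optional[float] = None
    mother_liquor: Optional[str] = None
    space_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.crystallization_pH is not None and not (
            0.0 <= self.crystallization_pH <= 14.0
        ):
            raise ValueError(f"pH out of [0,14]: {self.crystallization_pH}")


@dataclass
class StructureModel:
    """A parsed multi-model coordinate set with crystal metadata."""

    metadata: CrystalMetadata
    models: list[int]
    residues: dict[int, dict[tuple[str, int, str], ResidueView]]

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("structure must contain at least one model")

    @property
    def first_model(self) -> int:
        return self.models[0]

    def chains(self, model_number: Optional[int] = None) -> list[str]:
        mn = self.first_model if model_number is None else model_number
        seen: dict[str, None] = {}
        for (chain, _, _) in self.residues[mn]:
            seen.setdefault(chain, None)
        return list(seen)

    def iter_residues(self, model_number: Optional[int] = None) -> Iterable[ResidueView]:
        mn = self.first_model if model_number is None else model_number
        return self.residues[mn].values()

    def het_residues(
        self, residue_names: Iterable[str] = ANION_RESIDUES, model_number: Optional[int] = None
    ) -> list[ResidueView]:
        names = set(residue_names)
        return [r for r in self.iter_residues(model_number) if r.residue_name in names]


# --- pH token parsing -------------------------------------------------------

_PH_RE = re.compile(
    r"\bPH\b(?:\s+RANGE)?\s*[:=]?\s*"
    r"(\d{1,2}(?:[.,]\d+)?)"
    r"(?:\s*[-–]\s*(\d{1,2}(?:[.,]\d+)?))?",
    re.IGNORECASE,
)


def parse_ph_token(text: str) -> tuple[Optional[float], Optional[str]]:
    """Find a pH value (or range midpoint) in free text.

    Returns (value, range_note); both None if no parseable token.  A value
    outside [0, 14] is rejected with a warning rather than propagated.
    """
    m = _PH_RE.search(text)
    if not m:
        return None, None
    try:
        lo = float(m.group(1).replace(",", "."))
        hi = float(m.group(2).replace(",", ".")) if m.group(2) else None
    except ValueError:
        logger.warning("malformed pH token in %r", m.group(0))
        return None, None
    value = lo if hi is None else (lo + hi) / 2.0
    if not (0.0 <= value <= 14.0):
        logger.warning("pH token %s outside [0,14]; treating as missing", value)
        return None, None
    note = f"pH range {m.group(1)}-{m.group(2)}" if hi is not None else None
    return value, note


def _metadata_from_pdb_text(text: str, pdb_id: str = "") -> CrystalMetadata:
    remark280 = [
        line[len("REMARK 280"):].strip()
        for line in text.splitlines()
        if line.startswith("REMARK 280")
    ]
    blob = " ".join(remark280)
    ph, note = parse_ph_token(blob)
    liquor = blob or None
    if note and liquor:
        liquor = f"{liquor} [{note}]"
    sg = None
    for line in text.splitlines():
        if line.startswith("CRYST1") and len(line) >= 66:
            sg = line[55:66].strip() or None
    if not pdb_id:
        for line in text.splitlines():
            if line.startswith("HEADER") and len(line) >= 66:
                pdb_id = line[62:66].strip()
    return CrystalMetadata(
        pdb_id=pdb_id, crystallization_pH=ph, mother_liquor=liquor, space_group=sg
    )


def _metadata_from_mmcif(doc: "gemmi.cif.Document") -> CrystalMetadata:
    block = doc.sole_block()
    pdb_id = (block.find_value("_entry.id") or block.name or "").strip("?. ")
    ph_raw = block.find_value("_exptl_crystal_grow.pH")
    details = block.find_value("_exptl_crystal_grow.pdbx_details")
    sg = block.find_value("_symmetry.space_group_name_H-M")

    def _unquote(v: Optional[str]) -> Optional[str]:
        if v is None:
            return None
        v = v.strip()
        if v in ("?", "."):
            return None
        return v.strip("'\"")

    ph_raw, details, sg = _unquote(ph_raw), _unquote(details), _unquote(sg)
    ph: Optional[float] = None
    note = None
    if ph_raw is not None:
        try:
            ph = float(ph_raw)
        except ValueError:
            ph, note = parse_ph_token(f"pH {ph_raw}")
        if ph is not None and not (0.0 <= ph <= 14.0):
            logger.warning("mmCIF pH %s outside [0,14]; treating as missing", ph)
            ph = None
    if ph is None and details:
        ph, note = parse_ph_token(details)
    liquor = details
    if note:
        liquor = f"{liquor} [{note}]" if liquor else f"[{note}]"
    return CrystalMetadata(
        pdb_id=pdb_id, crystallization_pH=ph, mother_liquor=liquor, space_group=sg
    )


def extract_crystal_pH(path: str | Path, format: str = "auto") -> CrystalMetadata:
    """Extract crystallization metadata (pdb_id, pH, mother liquor, space group).

    PDB: REMARK 280 free text is scanned for a pH token.  mmCIF: the
    ``_exptl_crystal_grow.pH`` value is used, falling back to a token scan of
    ``pdbx_details``.  When nothing parses, pH is None (missing), never 7.
    """
    path = Path(path)
    fmt = _resolve_format(path, format)
    if fmt == "mmcif":
        doc = gemmi.cif.read(str(path))
        return _metadata_from_mmcif(doc)
    return _metadata_from_pdb_text(path.read_text())


def _resolve_format(path: Path, format: str) -> str:
    if format not in ("pdb", "mmcif", "auto"):
        raise ValueError(f"unknown format {format!r}")
    if format != "auto":
        return format
    suffix = path.name.lower()
    if suffix.endswith((".cif", ".mmcif", ".cif.gz")):
        return "mmcif"
    return "pdb"


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    All ATOM and HETATM records are kept, including waters and the anions
    (sulfate, glycerol) needed by the contact analysis.  Altlocs and
    occupancies are preserved.  Residues are addressed by author numbering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, format)
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc

    metadata = extract_crystal_pH(path, format=fmt)

    models: list[int] = []
    residues: dict[int, dict[tuple[str, int, str], ResidueView]] = {}
    n_atoms = 0
    for i, model in enumerate(st):
        mn = int(model.num) if str(model.num).isdigit() else i + 1
        models.append(mn)
        table: dict[tuple[str, int, str], ResidueView] = {}
        for chain in model:
            for res in chain:
                icode = res.seqid.icode.strip()
                key = (chain.name, res.seqid.num, icode)
                view = table.get(key)
                if view is None:
                    view = ResidueView(
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        residue_name=res.name,
                        insertion_code=icode,
                    )
                    table[key] = view
                for atom in res:
                    n_atoms += 1
                    view.atoms.append(
                        AtomRecord(
                            atom_name=atom.name,
                            element=atom.element.name,
                            coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                            altloc=atom.altloc if atom.altloc != "\x00" else "",
                            occupancy=min(max(atom.occ, 0.0), 1.0),
                            chain_id=chain.name,
                            residue_number=res.seqid.num,
                            insertion_code=icode,
                            residue_name=res.name,
                            model_number=mn,
                        )
                    )
        residues[mn] = table
    if n_atoms == 0:
        raise StructureParseError(f"{path}: no atoms found")
    return StructureModel(metadata=metadata, models=models, residues=residues)


def select_residue(
    model: StructureModel,
    chain_id: str,
    residue_number: int,
    insertion_code: str = "",
    model_number: Optional[int] = None,
    require_name: Optional[str] = None,
) -> ResidueView:
    """Select one residue by author numbering; errors list available chains."""
    mn = model.first_model if model_number is None else model_number
    if mn not in model.residues:
        raise ResidueNotFoundError(f"model {mn} not present (models: {model.models})")
    key = (chain_id, residue_number, insertion_code)
    view = model.residues[mn].get(key)
    if view is None:
        raise ResidueNotFoundError(
            f"residue {chain_id}/{residue_number}{insertion_code} not found; "
            f"available chains: {', '.join(model.chains(mn)) or '(none)'}"
        )
    if require_name is not None and view.residue_name != require_name:
        raise ValueError(
            f"residue {chain_id}/{residue_number} is {view.residue_name}, "
            f"expected {require_name}"
        )
    return view


# --- minimal PDB fixture writer --------------------------------------------

def _format_atom_name(name: str) -> str:
    # PDB columns 13-16: names of <4 chars start in column 14.
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3}"


def write_pdb_fixture(
    atoms: Iterable[AtomRecord],
    path: str | Path,
    remarks: Iterable[str] = (),
    het_residue_names: Iterable[str] = ANION_RESIDUES + WATER_RESIDUES,
) -> Path:
    """Write AtomRecords as a minimal PDB file (REMARK 280/ATOM/HETATM/END).

    Coordinates are written at 1e-3 A precision (the PDB fixed format), which
    bounds the write-read round trip error.
    """
    path = Path(path)
    het = set(het_residue_names)
    lines: list[str] = []
    for remark in remarks:
        lines.append(f"REMARK 280 {remark}"[:80])
    serial = 0
    for atom in atoms:
        serial += 1
        record = "HETATM" if atom.residue_name in het else "ATOM  "
        x, y, z = atom.coords
        lines.append(
            f"{record}{serial:>5} {_format_atom_name(atom.atom_name)}"
            f"{atom.altloc or ' '}{atom.residue_name:<3} {atom.chain_id[:1]}"
            f"{atom.residue_number:>4}{atom.insertion_code or ' '}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
            f"          {atom.element:>2}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
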