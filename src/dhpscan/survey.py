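"""Rotamer survey: per-subunit chi1 calls, concordance, anion contacts, pH test.

The survey asks whether the chi1 rotamer of the phosphorylatable His in
HisKA-family histidine kinases tracks crystallization pH.  It runs in two
modes:

* **manifest mode** — tallies the per-subunit rotamer labels and pH values of
  a curated survey manifest (the 28 HisKA entries ship as package data), with
  no coordinate files needed;
* **coordinate mode** — measures chi1 from local PDB/mmCIF files, classifies
  each qualifying altloc conformer independently, and can be checked
  entry-by-entry against the manifest labels.

Association between rotamer class and pH uses a two-sided exact test on the
2x2 table (pH at or below a threshold vs above) x (gauche- vs trans), computed
by hypergeometric enumeration from log-factorials.  The pH-gating hypothesis
this probes places the switch boundary between pH 5.2 and 6.5, so the default
threshold is 6.5.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from dhpscan.geometry import (
    DEFAULT_CONTACT_CUTOFF,
    DEFAULT_PARTITION,
    RotamerPartition,
    chi1 as compute_chi1,
    contact_search,
)
from dhpscan.structures import (
    ANION_RESIDUES,
    ResidueNotFoundError,
    ResidueView,
    StructureModel,
)

__all__ = [
    "RotamerCall",
    "SurveyTable",
    "AssociationResult",
    "ManifestEntry",
    "load_manifest",
    "load_selectors",
    "assign_rotamers",
    "dimer_concordance",
    "annotate_anion_coordination",
    "compile_survey",
    "fisher_exact_2x2",
    "test_ph_association",
    "DEFAULT_PH_THRESHOLD",
]

logger = logging.getLogger(__name__)

# pH-gating boundary under test: switch claimed between 5.2 and 6.5.
DEFAULT_PH_THRESHOLD = 6.5

# Alternate conformers below this occupancy do not yield a rotamer call.
MIN_ALTLOC_OCCUPANCY = 0.2

IMIDAZOLE_NITROGENS = ("ND1", "NE2")
ANION_PARTNER_ELEMENTS = ("O", "S")


@dataclass(frozen=True)
class RotamerCall:
    """One chi1 rotamer call for one kinase subunit / alternate conformer."""

    pdb_id: str
    protein: str
    chain_id: str
    residue_number: int
    altloc: str
    rotamer: str
    chi1: Optional[float] = None
    crystallization_pH: Optional[float] = None
    anion_coordinated: Optional[bool] = None  # None = not evaluated
    source: str = "coordinates"  # or "manifest"


@dataclass
class SurveyTable:
    """All rotamer calls of a survey, with per-structure concordance labels."""

    calls: list[RotamerCall] = field(default_factory=list)
    concordance: dict[str, str] = field(default_factory=dict)
    missing_structures: list[str] = field(default_factory=list)

    @property
    def counts(self) -> Counter:
        return Counter(c.rotamer for c in self.calls)

    @property
    def concordance_tally(self) -> Counter:
        return Counter(self.concordance.values())

    def structures(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.calls:
            seen.setdefault(c.pdb_id, None)
        return list(seen)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "pdb_id": c.pdb_id,
                "protein": c.protein,
                "chain": c.chain_id,
                "residue": c.residue_number,
                "altloc": c.altloc,
                "chi1": c.chi1,
                "rotamer": c.rotamer,
                "pH": c.crystallization_pH,
                "anion_coordinated": c.anion_coordinated,
                "source": c.source,
            }
            for c in self.calls
        ]
        df = pd.DataFrame(
            rows,
            columns=[
                "pdb_id", "protein", "chain", "residue", "altloc",
                "chi1", "rotamer", "pH", "anion_coordinated", "source",
            ],
        )
        return df.sort_values(["pdb_id", "chain", "altloc"], kind="stable").reset_index(
            drop=True
        )

    def summary(self) -> dict:
        counts = self.counts
        return {
            "n_calls": len(self.calls),
            "n_structures": len(self.structures()),
            "counts": {
                "gauche-": counts.get("gauche-", 0),
                "gauche+": counts.get("gauche+", 0),
                "trans": counts.get("trans", 0),
            },
            "concordance": dict(self.concordance_tally),
            "missing_structures": list(self.missing_structures),
        }


@dataclass
class AssociationResult:
    """Exact 2x2 association between pH bin and rotamer class."""

    table: np.ndarray  # rows: pH <= threshold / > threshold; cols: gauche- / trans
    p_value: float
    odds_ratio: float  # may be inf or 0
    threshold_ph: float
    degenerate: bool = False
    n_excluded_missing_ph: int = 0
    n_excluded_gauche_plus: int = 0

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=int)
        if self.table.shape != (2, 2) or (self.table < 0).any():
            raise ValueError("table must be a nonnegative 2x2")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value out of (0,1]: {self.p_value}")

    def to_dict(self) -> dict:
        return {
            "table": self.table.tolist(),
            "p_value": self.p_value,
            "odds_ratio": self.odds_ratio,
            "threshold_ph": self.threshold_ph,
            "degenerate": self.degenerate,
            "n_excluded_missing_ph": self.n_excluded_missing_ph,
            "n_excluded_gauche_plus": self.n_excluded_gauche_plus,
        }


# --- manifest ---------------------------------------------------------------

@dataclass(frozen=True)
class ManifestEntry:
    pdb_id: str
    protein: str
    ph_text: str
    ph_value: Optional[float]
    subunit_labels: tuple[tuple[str, ...], ...]  # one tuple of labels per subunit
    mother_liquor: str = ""


def _parse_ph_field(text: str) -> Optional[float]:
    text = text.strip().replace(",", ".")
    if not text or text.upper() in ("NA", "MISSING", "?"):
        return None
    if "-" in text[1:]:
        lo_s, hi_s = text.split("-", 1)
        lo, hi = float(lo_s), float(hi_s)
        return (lo + hi) / 2.0
    return float(text)


def _normalize_label(token: str) -> str:
    t = token.strip().lower().replace("−", "-").replace("–", "-")
    t = t.replace(" ", "")
    if t in ("gauche-", "gauche"):
        return "gauche-"
    if t == "gauche+":
        return "gauche+"
    if t == "trans":
        return "trans"
    raise ValueError(f"unrecognized rotamer label {token!r}")


def parse_rotamer_notation(text: str) -> tuple[tuple[str, ...], ...]:
    """Parse per-subunit rotamer notation like ``gauche-/gauche- & trans``.

    Subunits are slash-separated; ``&`` within one subunit marks alternate
    conformers of that subunit (double-conformed side chains).
    """
    subunits = []
    for part in text.split("/"):
        labels = tuple(_normalize_label(tok) for tok in part.split("&"))
        if not labels:
            raise ValueError(f"empty subunit in {text!r}")
        subunits.append(labels)
    if not subunits:
        raise ValueError("no subunits in rotamer notation")
    return tuple(subunits)


def load_manifest(path: str | Path | None = None) -> list[ManifestEntry]:
    """Load the survey manifest (default: the packaged 28-entry HisKA table)."""
    if path is None:
        source = resources.files("dhpscan.data").joinpath("hiska_survey_manifest.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    df = pd.read_csv(pd.io.common.StringIO(text), sep="\t", dtype=str).fillna("")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            ManifestEntry(
                pdb_id=row["pdb_id"].strip(),
                protein=row["protein"].strip(),
                ph_text=row["ph"].strip(),
                ph_value=_parse_ph_field(row["ph"]),
                subunit_labels=parse_rotamer_notation(row["rotamers"]),
                mother_liquor=row.get("mother_liquor", "").strip(),
            )
        )
    return entries


def load_selectors(path: str | Path | None = None) -> dict:
    """Load the protein -> phospho-His residue-number selector configuration."""
    if path is None:
        source = resources.files("dhpscan.data").joinpath("selectors.json")
        raw = json.loads(source.read_text())
    else:
        raw = json.loads(Path(path).read_text())
    return raw["proteins"]


# --- coordinate-mode calls --------------------------------------------------

def assign_rotamers(
    model: StructureModel,
    his_residue: int,
    pdb_id: str = "",
    protein: str = "",
    partition: RotamerPartition = DEFAULT_PARTITION,
    crystallization_pH: Optional[float] = None,
    model_number: Optional[int] = None,
) -> list[RotamerCall]:
    """One rotamer call per kinase subunit per qualifying altloc conformer.

    Every chain carrying a His at ``his_residue`` counts as a subunit.  Each
    altloc group with occupancy >= 0.2 and a complete N/CA/CB/CG set yields an
    independent call; lower-occupancy conformers are skipped with a log line.
    gauche+ calls are permitted but flagged (none occur in surveyed HisKA
    structures).
    """
    if crystallization_pH is None:
        crystallization_pH = model.metadata.crystallization_pH
    calls: list[RotamerCall] = []
    for res in model.iter_residues(model_number):
        if res.residue_number != his_residue or res.residue_name != "HIS":
            continue
        for label, group in sorted(res.altloc_groups().items()):
            occ = res.group_occupancy(label)
            if occ < MIN_ALTLOC_OCCUPANCY:
                logger.info(
                    "%s %s/%d altloc %r occupancy %.2f < %.2f: skipped",
                    pdb_id, res.chain_id, his_residue, label, occ, MIN_ALTLOC_OCCUPANCY,
                )
                continue
            try:
                angle = compute_chi1({name: a.xyz for name, a in group.items()})
            except KeyError as exc:
                logger.warning(
                    "%s %s/%d altloc %r: %s", pdb_id, res.chain_id, his_residue, label, exc
                )
                continue
            rotamer = partition.classify(angle.value)
            if rotamer == "gauche+":
                logger.warning(
                    "%s %s/%d altloc %r: unexpected gauche+ call (chi1 %.1f)",
                    pdb_id, res.chain_id, his_residue, label, angle.value,
                )
            calls.append(
                RotamerCall(
                    pdb_id=pdb_id or model.metadata.pdb_id,
                    protein=protein,
                    chain_id=res.chain_id,
                    residue_number=his_residue,
                    altloc=label,
                    rotamer=rotamer,
                    chi1=angle.value,
                    crystallization_pH=crystallization_pH,
                )
            )
    if not calls:
        raise ResidueNotFoundError(
            f"no His {his_residue} with measurable chi1 in any chain "
            f"(chains: {', '.join(model.chains(model_number))})"
        )
    return calls


def dimer_concordance(calls: Sequence[RotamerCall]) -> str:
    """Concordance label for one structure's calls.

    ``identical`` — every subunit carries a single label and all labels agree;
    ``mixed-altloc`` — some subunit carries two conformers with different
    labels; ``distinct`` — subunits disagree.  Single-subunit structures are
    ``not-evaluated``.
    """
    by_subunit: dict[str, set[str]] = {}
    for c in calls:
        by_subunit.setdefault(c.chain_id, set()).add(c.rotamer)
    if len(by_subunit) < 2:
        return "not-evaluated"
    if any(len(labels) > 1 for labels in by_subunit.values()):
        return "mixed-altloc"
    flat = {next(iter(labels)) for labels in by_subunit.values()}
    return "identical" if len(flat) == 1 else "distinct"


def annotate_anion_coordination(
    model: StructureModel,
    call: RotamerCall,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    anion_residues: Iterable[str] = ANION_RESIDUES,
) -> RotamerCall:
    """Set the anion-coordination flag on a coordinate-mode call.

    True iff any O/S atom of a sulfate (or configured anion/polyol residue)
    lies within ``cutoff`` of the imidazole Nd1 or Ne2 of the called altloc
    conformer.  If those nitrogens are absent the call stays not-evaluated.
    """
    res = None
    for r in model.iter_residues():
        if (
            r.chain_id == call.chain_id
            and r.residue_number == call.residue_number
            and r.residue_name == "HIS"
        ):
            res = r
            break
    if res is None:
        raise ResidueNotFoundError(f"call residue {call.chain_id}/{call.residue_number}")
    group = res.altloc_groups().get(call.altloc, {})
    donors = [
        (name, group[name].xyz) for name in IMIDAZOLE_NITROGENS if name in group
    ]
    if not donors:
        return replace(call, anion_coordinated=None)
    partners = [
        (f"{r.residue_name}:{a.atom_name}", a.xyz)
        for r in model.het_residues(anion_residues)
        for a in r.atoms
        if a.element in ANION_PARTNER_ELEMENTS
    ]
    contacts = contact_search(donors, partners, cutoff=cutoff)
    return replace(call, anion_coordinated=bool(contacts))


# --- survey compilation -----------------------------------------------------

def _manifest_calls(entry: ManifestEntry) -> list[RotamerCall]:
    calls = []
    for i, labels in enumerate(entry.subunit_labels):
        chain = chr(ord("A") + i)
        for j, label in enumerate(labels):
            altloc = "" if len(labels) == 1 else chr(ord("A") + j)
            calls.append(
                RotamerCall(
                    pdb_id=entry.pdb_id,
                    protein=entry.protein,
                    chain_id=chain,
                    residue_number=-1,
                    altloc=altloc,
                    rotamer=label,
                    chi1=None,
                    crystallization_pH=entry.ph_value,
                    source="manifest",
                )
            )
    return calls


def compile_survey(
    manifest: Sequence[ManifestEntry],
    structures_dir: str | Path | None = None,
    selectors: Optional[dict] = None,
    partition: RotamerPartition = DEFAULT_PARTITION,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    annotate_anions: bool = False,
) -> SurveyTable:
    """Build the full survey table.

    With ``structures_dir`` unset the survey runs in manifest mode, turning
    the printed per-subunit labels into calls.  With a directory, each entry's
    ``<pdb_id>.pdb`` / ``.cif`` is read and chi1 measured; entries whose file
    is missing are recorded in ``missing_structures`` (counts then cover the
    present set and callers should signal a partial run).
    """
    from dhpscan.structures import read_structure  # local import to avoid cycle at init

    table = SurveyTable()
    for entry in manifest:
        if structures_dir is None:
            calls = _manifest_calls(entry)
        else:
            path = None
            for ext in (".pdb", ".ent", ".cif", ".mmcif"):
                cand = Path(structures_dir) / f"{entry.pdb_id}{ext}"
                if cand.exists():
                    path = cand
                    break
            if path is None:
                logger.warning("structure file for %s not found", entry.pdb_id)
                table.missing_structures.append(entry.pdb_id)
                continue
            if selectors is None:
                selectors = load_selectors()
            sel = selectors.get(entry.protein, {})
            his_residue = sel.get("his_residue")
            if his_residue is None:
                logger.warning("no His selector for %s (%s)", entry.pdb_id, entry.protein)
                table.missing_structures.append(entry.pdb_id)
                continue
            model = read_structure(path)
            try:
                calls = assign_rotamers(
                    model,
                    his_residue=int(his_residue),
                    pdb_id=entry.pdb_id,
                    protein=entry.protein,
                    partition=partition,
                    crystallization_pH=entry.ph_value,  # manifest pH is source of truth
                )
            except ResidueNotFoundError as exc:
                logger.warning("%s: %s", entry.pdb_id, exc)
                table.missing_structures.append(entry.pdb_id)
                continue
            if annotate_anions:
                calls = [
                    annotate_anion_coordination(model, c, cutoff=contact_cutoff)
                    for c in calls
                ]
        table.calls.extend(calls)
        table.concordance[entry.pdb_id] = dimer_concordance(calls)
    return table


# --- exact association test -------------------------------------------------

def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> AssociationResult:
    """Two-sided exact test on a 2x2 table by hypergeometric enumeration.

    With margins fixed, every admissible table's probability is computed from
    log-factorials and those no more probable than the observed one (within a
    1e-7 relative tie tolerance) are summed.  A zero margin makes the table
    degenerate: p = 1 by convention, flagged.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative integer 2x2 table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2

    def _odds_ratio() -> float:
        if b * c == 0:
            return math.inf if a * d > 0 else math.nan
        return (a * d) / (b * c)

    if 0 in (r1, r2, c1, c2):
        return AssociationResult(
            table=t, p_value=1.0, odds_ratio=_odds_ratio(),
            threshold_ph=math.nan, degenerate=True,
        )

    denom = _log_binom(n, c1)

    def log_prob(x: int) -> float:
        return _log_binom(r1, x) + _log_binom(r2, c1 - x) - denom

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = math.exp(log_prob(a))
    total = 0.0
    for x in range(lo, hi + 1):
        p = math.exp(log_prob(x))
        if p <= p_obs * (1.0 + 1e-7):
            total += p
    return AssociationResult(
        table=t,
        p_value=min(total, 1.0),
        odds_ratio=_odds_ratio(),
        threshold_ph=math.nan,
    )


def test_ph_association(
    survey: SurveyTable, threshold_ph: float = DEFAULT_PH_THRESHOLD
) -> AssociationResult:
    """Exact test of rotamer class against a pH split of the survey calls.

    Calls with missing pH or a gauche+ label are excluded (and counted in the
    result, never silently dropped).  Rows: pH <= threshold / pH > threshold;
    columns: gauche- / trans.
    """
    n_missing = sum(1 for c in survey.calls if c.crystallization_pH is None)
    n_gplus = sum(
        1
        for c in survey.calls
        if c.crystallization_pH is not None and c.rotamer == "gauche+"
    )
    usable = [
        c
        for c in survey.calls
        if c.crystallization_pH is not None and c.rotamer in ("gauche-", "trans")
    ]
    if not usable:
        raise ValueError("no calls with known pH and gauche-/trans label")
    t = np.zeros((2, 2), dtype=int)
    for c in usable:
        row = 0 if c.crystallization_pH <= threshold_ph else 1
        col = 0 if c.rotamer == "gauche-" else 1
        t[row, col] += 1
    result = fisher_exact_2x2(t)
    result.threshold_ph = threshold_ph
    result.n_excluded_missing_ph = n_missing
    result.n_excluded_gauche_plus = n_gplus
    if t[0].sum() == 0 or t[1].sum() == 0:
        result.degenerate = True
    return result
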