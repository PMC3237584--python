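"""Structure standardization ("washing") and dataset curation.

Molecule collections destined for metabolite-likeness modelling arrive as
SDF or SMILES files of uneven quality: salt forms, charged species,
explicit hydrogens, duplicate entries, and compounds (very large molecules,
tiny ions, annotated drugs) that do not belong in either the metabolite or
the background class.  This module reads such collections, standardizes
every structure to a canonical, largest-fragment, neutralized, stereo-free
form, and applies the curation filters — molecular-weight ceiling, minimum
atom count, drug-annotation removal, and cross-set deduplication — while
keeping an auditable per-stage removal report.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

# RDKit is chatty about every unparseable entry; we log skips ourselves.
RDLogger.DisableLog("rdApp.error")

METABOLITE = "metabolite"
NON_METABOLITE = "non_metabolite"


@dataclass
class MoleculeRecord:
    """One compound: identifier, canonical structure, optional label/annotations."""

    id: str
    structure: str
    label: str | None = None
    annotations: dict[str, str] = field(default_factory=dict)
    mol_weight: float | None = None

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.structure)
        if m is None:
            raise ValueError(f"unparseable structure for {self.id!r}: {self.structure!r}")
        return m


@dataclass
class CurationConfig:
    max_mol_weight: float = 1000.0
    min_atom_count: int = 3
    drug_annotation_fields: list[str] = field(
        default_factory=lambda: ["Taxonomy Family", "Taxonomy Sub Class"]
    )
    drug_patterns: list[str] = field(default_factory=lambda: ["drug"])

    def __post_init__(self) -> None:
        if self.max_mol_weight <= 0:
            raise ValueError("max_mol_weight must be positive")
        if self.min_atom_count < 1:
            raise ValueError("min_atom_count must be >= 1")


@dataclass
class CurationReport:
    """Per-stage removal counts; input = retained + sum(removed)."""

    removed: dict[str, int] = field(default_factory=dict)
    retained: int = 0

    @property
    def input_count(self) -> int:
        return self.retained + sum(self.removed.values())

    def to_rows(self) -> list[dict]:
        rows = [{"stage": k, "removed": v} for k, v in self.removed.items()]
        rows.append({"stage": "retained", "removed": self.retained})
        return rows


def load_molecules(path: str | Path, format: str = "smiles") -> list[MoleculeRecord]:
    """Read an SDF or SMILES file into raw (unwashed) records.

    Unparseable entries are logged and skipped; a file with zero parseable
    entries raises ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records: list[MoleculeRecord] = []
    skipped = 0
    if format == "smiles":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"M{i + 1}"
            if Chem.MolFromSmiles(smiles) is None:
                logger.warning("skipping unparseable SMILES at line %d: %s", i + 1, smiles)
                skipped += 1
                continue
            records.append(MoleculeRecord(id=mol_id, structure=smiles))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.warning("skipping unparseable SDF block %d", i + 1)
                skipped += 1
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"M{i + 1}"
            annotations = {k: str(v) for k, v in mol.GetPropsAsDict().items()}
            records.append(
                MoleculeRecord(id=name, structure=Chem.MolToSmiles(mol), annotations=annotations)
            )
    else:
        raise ValueError(f"unknown format {format!r}")
    if not records:
        raise ValueError(f"no parseable molecules in {path} ({skipped} skipped)")
    if skipped:
        logger.info("loaded %d molecules from %s (%d skipped)", len(records), path, skipped)
    return records


_UNCHARGER = rdMolStandardize.Uncharger()


def wash(record: MoleculeRecord) -> MoleculeRecord:
    """Standardize a structure: largest fragment, neutralized, stereo-free, canonical.

    Keeps only the largest connected fragment (ties broken by heavy-atom
    count, then by canonical SMILES order), removes counter-ions that way,
    neutralizes charges where chemically valid (permanently charged centres
    such as quaternary nitrogen stay charged), strips stereochemistry and
    explicit hydrogens, and canonicalizes.  Idempotent.
    """
    mol = record.mol()
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if not frags:
        raise ValueError(f"no atoms left after fragment selection for {record.id!r}")

    def frag_key(m: Chem.Mol) -> tuple:
        # larger first; among equals prefer lexicographically smaller SMILES
        return (-m.GetNumAtoms(), -m.GetNumHeavyAtoms(), Chem.MolToSmiles(m))

    best = sorted(frags, key=frag_key)[0]
    if best.GetNumAtoms() == 0:
        raise ValueError(f"no atoms left after fragment selection for {record.id!r}")
    best = _UNCHARGER.uncharge(best)
    Chem.RemoveStereochemistry(best)
    best = Chem.RemoveHs(best)
    smiles = Chem.MolToSmiles(best)
    return MoleculeRecord(
        id=record.id,
        structure=smiles,
        label=record.label,
        annotations=dict(record.annotations),
        mol_weight=Descriptors.MolWt(best),
    )


def wash_all(records: Iterable[MoleculeRecord]) -> list[MoleculeRecord]:
    return [wash(r) for r in records]


def _total_atom_count(record: MoleculeRecord) -> int:
    mol = record.mol()
    return mol.GetNumHeavyAtoms() + sum(a.GetTotalNumHs() for a in mol.GetAtoms())


def apply_filters(
    mols: Sequence[MoleculeRecord], cfg: CurationConfig
) -> tuple[list[MoleculeRecord], CurationReport]:
    """Molecular-weight ceiling then minimum total atom count (H included)."""
    report = CurationReport(removed={"mol_weight": 0, "atom_count": 0})
    kept: list[MoleculeRecord] = []
    for rec in mols:
        mw = rec.mol_weight if rec.mol_weight is not None else Descriptors.MolWt(rec.mol())
        if mw > cfg.max_mol_weight:
            report.removed["mol_weight"] += 1
            continue
        if _total_atom_count(rec) < cfg.min_atom_count:
            report.removed["atom_count"] += 1
            continue
        kept.append(rec)
    report.retained = len(kept)
    return kept, report


def remove_annotated_drugs(
    mols: Sequence[MoleculeRecord], cfg: CurationConfig
) -> tuple[list[MoleculeRecord], CurationReport]:
    """Drop records whose configured annotation fields match any drug pattern.

    Matching is case-insensitive substring; records lacking the fields are
    retained.
    """
    patterns = [p.lower() for p in cfg.drug_patterns]
    report = CurationReport(removed={"drug_annotation": 0})
    kept: list[MoleculeRecord] = []
    for rec in mols:
        values = [
            rec.annotations[f].lower() for f in cfg.drug_annotation_fields if f in rec.annotations
        ]
        if patterns and any(p in v for v in values for p in patterns):
            report.removed["drug_annotation"] += 1
        else:
            kept.append(rec)
    report.retained = len(kept)
    return kept, report


def _canonical(structure: str) -> str:
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable structure: {structure!r}")
    return Chem.MolToSmiles(mol)


def deduplicate_against(
    mols: Sequence[MoleculeRecord], reference: Sequence[MoleculeRecord]
) -> tuple[list[MoleculeRecord], CurationReport]:
    """Remove from ``mols`` every structure present in ``reference``.

    Comparison is on canonical SMILES, not identifiers, so two spellings of
    one molecule still collide.
    """
    ref = {_canonical(r.structure) for r in reference}
    report = CurationReport(removed={"duplicate_of_reference": 0})
    kept: list[MoleculeRecord] = []
    for rec in mols:
        if _canonical(rec.structure) in ref:
            report.removed["duplicate_of_reference"] += 1
        else:
            kept.append(rec)
    report.retained = len(kept)
    return kept, report


def load_annotations_csv(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Attach annotations from a sidecar CSV (column ``id`` + one column per field)."""
    with open(path, newline="") as fh:
        by_id = {row["id"]: row for row in csv.DictReader(fh)}
    for rec in records:
        row = by_id.get(rec.id)
        if row:
            rec.annotations.update({k: v for k, v in row.items() if k != "id"})


def write_smiles(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.structure}\t{rec.id}\n")


def write_report(reports: dict[str, CurationReport], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["dataset", "stage", "removed", "retained"])
        writer.writeheader()
        for name, rep in reports.items():
            for stage, n in rep.removed.items():
                writer.writerow({"dataset": name, "stage": stage, "removed": n, "retained": ""})
            writer.writerow({"dataset": name, "stage": "retained", "removed": "", "retained": rep.retained})
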