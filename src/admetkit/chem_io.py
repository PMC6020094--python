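"""Reading, washing and writing molecules.

The accepted input formats are SMILES files (one molecule per line with an
optional name), SDF V2000 and CSV tables with ``id``/``smiles`` columns.
Washing standardizes a structure in three steps: disconnect metal--heteroatom
bonds in simple salts, keep the largest remaining fragment, and normalize
hydrogens (explicit hydrogens on the stored structure, canonical SMILES stored
without explicit-H notation).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

# Reason codes used in WashReport.removals
UNPARSEABLE = "UNPARSEABLE"
EMPTY_AFTER_WASH = "EMPTY_AFTER_WASH"
DUPLICATE_ID = "DUPLICATE_ID"

# Alkali / alkaline-earth metals whose bonds to O/N/S are cleaved before
# fragment selection ("simple salts").
_SALT_METALS = {3, 11, 19, 37, 55, 4, 12, 20, 38, 56}
_SALT_PARTNERS = {7, 8, 16}


class ParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class EmptyInputError(ValueError):
    """Raised when an input file yields zero parseable molecules."""


@dataclass
class MoleculeRecord:
    """One parsed molecule.

    ``smiles`` is the canonical SMILES of ``structure``; ``source_index`` is
    the 0-based position in the originating file.
    """

    id: str
    smiles: str
    structure: Chem.Mol
    name: str | None = None
    source_index: int = 0
    properties: dict = field(default_factory=dict)


@dataclass
class WashReport:
    input_count: int = 0
    parsed_count: int = 0
    washed_count: int = 0
    removals: list[tuple[str, str]] = field(default_factory=list)


def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES for *smiles*.

    Identical molecular graphs map to identical strings and the function is
    idempotent. Raises :class:`ParseError` naming the offending input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def _disconnect_simple_salts(mol: Chem.Mol) -> Chem.Mol:
    """Cleave bonds between alkali/alkaline-earth metals and O/N/S."""
    em = Chem.RWMol(mol)
    to_remove = []
    for bond in em.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        za, zb = a.GetAtomicNum(), b.GetAtomicNum()
        if (za in _SALT_METALS and zb in _SALT_PARTNERS) or (
            zb in _SALT_METALS and za in _SALT_PARTNERS
        ):
            to_remove.append((a.GetIdx(), b.GetIdx()))
    if not to_remove:
        return mol
    for ai, bi in to_remove:
        atom_a, atom_b = em.GetAtomWithIdx(ai), em.GetAtomWithIdx(bi)
        metal, other = (atom_a, atom_b) if atom_a.GetAtomicNum() in _SALT_METALS else (atom_b, atom_a)
        em.RemoveBond(ai, bi)
        # ionic charges after heterolytic cleavage toward the heteroatom
        metal.SetFormalCharge(metal.GetFormalCharge() + 1)
        other.SetFormalCharge(other.GetFormalCharge() - 1)
    out = em.GetMol()
    Chem.SanitizeMol(out)
    return out


def _fragment_key(frag: Chem.Mol) -> tuple:
    # largest by heavy atoms, ties by molecular weight, then canonical SMILES
    return (
        frag.GetNumHeavyAtoms(),
        Descriptors.MolWt(frag),
        Chem.MolToSmiles(frag),
    )


def wash_molecule(record: MoleculeRecord) -> MoleculeRecord | tuple[str, str]:
    """Wash one molecule; returns the washed record or a removal tuple.

    Steps: salt disconnection, largest-fragment retention, hydrogen
    normalization. A structure left without heavy atoms yields an
    ``EMPTY_AFTER_WASH`` removal. The operation is idempotent.
    """
    mol = _disconnect_simple_salts(record.structure)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    frags = [f for f in frags if f.GetNumHeavyAtoms() > 0]
    if not frags:
        return (record.id, EMPTY_AFTER_WASH)
    best = max(frags, key=_fragment_key)
    # explicit hydrogens live on the stored structure; the canonical SMILES
    # is written from the implicit-H form
    no_h = Chem.RemoveHs(best)
    smiles = Chem.MolToSmiles(no_h)
    structure = Chem.AddHs(no_h)
    return replace(record, smiles=smiles, structure=structure)


def wash_molecules(
    records: Iterable[MoleculeRecord], report: WashReport | None = None
) -> tuple[list[MoleculeRecord], WashReport]:
    report = report or WashReport()
    washed = []
    for rec in records:
        out = wash_molecule(rec)
        if isinstance(out, tuple):
            report.removals.append(out)
        else:
            washed.append(out)
    report.washed_count = len(washed)
    return washed, report


def _dedupe_ids(records: list[MoleculeRecord], report: WashReport) -> None:
    seen: dict[str, int] = {}
    for rec in records:
        if rec.id in seen:
            seen[rec.id] += 1
            new_id = f"{rec.id}_{seen[rec.id]}"
            report.removals.append((rec.id, DUPLICATE_ID))
            rec.id = new_id
            seen[new_id] = 0
        else:
            seen[rec.id] = 0


def _read_smi(path: Path) -> list[tuple[str, str | None, str | None]]:
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        rows.append((parts[0], parts[1].strip() if len(parts) > 1 else None, None))
    return rows


def _read_csv(path: Path) -> list[tuple[str, str | None, str | None, dict]]:
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "smiles" not in [f.lower() for f in reader.fieldnames]:
            raise ValueError(f"CSV input {path} needs a 'smiles' column")
        fmap = {f.lower(): f for f in reader.fieldnames}
        for i, row in enumerate(reader):
            smi = row[fmap["smiles"]]
            rid = row.get(fmap.get("id", ""), None) if "id" in fmap else None
            extra = {
                k: v
                for k, v in row.items()
                if k not in {fmap["smiles"], fmap.get("id")}
            }
            rows.append((smi, rid, None, extra))
    return rows


def read_molecules(
    path: str | Path, format: str | None = None, wash: bool = True
) -> tuple[list[MoleculeRecord], WashReport]:
    """Read molecules from *path* (``smi``, ``sdf`` or ``csv``).

    One record per parseable molecule in input order; unparseable entries are
    logged in the report, never silently dropped. Raises
    :class:`EmptyInputError` when nothing parses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "smi"
    format = format.lower()
    report = WashReport()
    records: list[MoleculeRecord] = []

    if format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            report.input_count += 1
            if mol is None:
                report.removals.append((f"mol{i}", UNPARSEABLE))
                continue
            rid = mol.GetProp("_Name").strip() if mol.HasProp("_Name") and mol.GetProp("_Name").strip() else f"mol{i}"
            records.append(
                MoleculeRecord(
                    id=rid,
                    smiles=Chem.MolToSmiles(mol),
                    structure=mol,
                    name=rid,
                    source_index=i,
                )
            )
    elif format in {"smi", "csv"}:
        if format == "smi":
            raw = [(s, n, None, {}) for s, n, _ in _read_smi(path)]
        else:
            raw = _read_csv(path)
        for i, (smi, rid, _name, extra) in enumerate(raw):
            report.input_count += 1
            mol = Chem.MolFromSmiles(smi) if smi else None
            if mol is None:
                report.removals.append((rid or f"mol{i}", UNPARSEABLE))
                continue
            records.append(
                MoleculeRecord(
                    id=rid if rid else f"mol{i}",
                    smiles=Chem.MolToSmiles(mol),
                    structure=mol,
                    name=rid,
                    source_index=i,
                    properties=extra,
                )
            )
    else:
        raise ValueError(f"unknown format: {format!r}")

    report.parsed_count = len(records)
    if report.parsed_count == 0:
        raise EmptyInputError(f"no parseable molecules in {path}")
    _dedupe_ids(records, report)
    if wash:
        records, report = wash_molecules(records, report)
    else:
        report.washed_count = report.parsed_count
    return records, report


def write_molecules(records: Sequence[MoleculeRecord], path: str | Path, format: str | None = None) -> None:
    """Write records as .smi or .sdf."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "smi"
    if format == "smi":
        with open(path, "w") as fh:
            for rec in records:
                fh.write(f"{rec.smiles} {rec.id}\n")
    elif format == "sdf":
        writer = Chem.SDWriter(str(path))
        for rec in records:
            mol = Chem.MolFromSmiles(rec.smiles)
            mol.SetProp("_Name", rec.id)
            writer.write(mol)
        writer.close()
    else:
        raise ValueError(f"unknown format: {format!r}")


def record_from_smiles(smiles: str, id: str = "query", wash: bool = True) -> MoleculeRecord:
    """Convenience constructor for a single washed record."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    rec = MoleculeRecord(id=id, smiles=Chem.MolToSmiles(mol), structure=mol)
    if wash:
        out = wash_molecule(rec)
        if isinstance(out, tuple):
            raise ParseError(f"molecule {id!r} empty after washing")
        return out
    return rec
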