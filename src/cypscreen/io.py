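"""Readers and writers for compound records (CSV, SMILES, SDF).

Malformed rows are collected into an error report and returned alongside
the parsed records -- never silently dropped.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence

from rdkit import Chem

from .records import CompoundRecord, Label, Source

CSV_COLUMNS = ["compound_id", "smiles", "source", "activity_value", "smiles_std", "label"]


def _record_from_row(row: dict, line: int) -> CompoundRecord:
    missing = {"compound_id", "smiles"} - set(k for k, v in row.items() if v not in (None, ""))
    if missing:
        raise ValueError(f"line {line}: missing {sorted(missing)}")
    value = row.get("activity_value")
    return CompoundRecord(
        compound_id=row["compound_id"],
        smiles_raw=row["smiles"],
        source=Source(row.get("source") or "library"),
        activity_value=float(value) if value not in (None, "") else None,
        smiles_std=row.get("smiles_std") or None,
        label=Label(row.get("label") or "unlabeled"),
    )


def read_csv(path) -> tuple:
    """Read records from CSV; returns (records, error report list)."""
    records, errors = [], []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "smiles" not in reader.fieldnames:
            raise ValueError(f"{path}: CSV header with a 'smiles' column is required")
        for i, row in enumerate(reader, start=2):
            try:
                records.append(_record_from_row(row, i))
            except (ValueError, KeyError) as exc:
                errors.append(str(exc))
    return records, errors


def write_csv(records: Sequence[CompoundRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.compound_id,
                    r.smiles_raw,
                    r.source.value,
                    "" if r.activity_value is None else r.activity_value,
                    r.smiles_std or "",
                    r.label.value,
                ]
            )


def read_smiles(path) -> tuple:
    """Read a .smi file (SMILES [whitespace] id per line)."""
    records, errors = [], []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"mol-{i:06d}"
            records.append(CompoundRecord(compound_id=cid, smiles_raw=smiles))
    return records, errors


def write_smiles(records: Sequence[CompoundRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f"{r.smiles_std or r.smiles_raw}\t{r.compound_id}\n")


def read_sdf(path) -> tuple:
    """Read records from an SDF; activity/source/label from SD tags."""
    records, errors = [], []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            errors.append(f"molecule {i}: unparseable SDF block")
            continue
        props = mol.GetPropsAsDict()
        cid = str(props.get("compound_id", mol.GetProp("_Name") if mol.HasProp("_Name") else "") or f"mol-{i:06d}")
        value = props.get("activity_value")
        records.append(
            CompoundRecord(
                compound_id=cid,
                smiles_raw=Chem.MolToSmiles(mol),
                source=Source(str(props.get("source", "library"))),
                activity_value=float(value) if value is not None else None,
                label=Label(str(props.get("label", "unlabeled"))),
            )
        )
    return records, errors


def write_sdf(records: Sequence[CompoundRecord], path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for r in records:
            mol = Chem.MolFromSmiles(r.smiles_std or r.smiles_raw)
            if mol is None:
                raise ValueError(f"cannot serialize unparseable SMILES for {r.compound_id}")
            mol.SetProp("_Name", r.compound_id)
            mol.SetProp("compound_id", r.compound_id)
            mol.SetProp("source", r.source.value)
            mol.SetProp("label", r.label.value)
            if r.activity_value is not None:
                mol.SetProp("activity_value", repr(r.activity_value))
            writer.write(mol)
    finally:
        writer.close()


_FORMATS = {
    "csv": (read_csv, write_csv),
    "smiles": (read_smiles, write_smiles),
    "sdf": (read_sdf, write_sdf),
}


def _infer_format(path, fmt: Optional[str]) -> str:
    if fmt:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    return {"smi": "smiles", "csv": "csv", "sdf": "sdf"}.get(suffix, "csv")


def read_compounds(path, fmt: Optional[str] = None) -> tuple:
    """Read records from CSV/SMILES/SDF; returns (records, error report)."""
    reader, _ = _FORMATS[_infer_format(path, fmt)]
    return reader(path)


def write_compounds(records: Sequence[CompoundRecord], path, fmt: Optional[str] = None) -> None:
    _, writer = _FORMATS[_infer_format(path, fmt)]
    writer(records, path)
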