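"""Serialization of dataset records to the eight-column CSV schema.

The on-disk layout is a (optionally gzip-compressed) RFC-4180 CSV with one
header row and eight columns in fixed order. List-valued cells are JSON
arrays inside quoted fields; the cid columns hold lists of lists, because a
single matched structure can carry several library identifiers. Empty
match lists are written as ``[]``. The reader applies the full round-trip
law and also tolerates the single-quoted Python-literal list dialect that
dataframe writers commonly produce.
"""

from __future__ import annotations

import ast
import csv
import gzip
import hashlib
import io
import json
from dataclasses import dataclass
from typing import List

from .errors import DatasetRowError, DatasetSchemaError
from .pipeline import DatasetRecord

COLUMNS = (
    "smiles",
    "chebi",
    "num_heavy_atoms",
    "exact_mol_wt",
    "core_superstructure_smiles",
    "core_superstructure_pubchem_cid",
    "rgroup_extended_smiles",
    "rgroup_extended_pubchem_cid",
)


@dataclass(frozen=True)
class CsvDialect:
    """Writing conventions: fixed column order, JSON list cells, 5-dp floats."""

    column_order: tuple = COLUMNS
    float_decimals: int = 5
    empty_list_token: str = "[]"

    def encode_list(self, values) -> str:
        return json.dumps(list(values), separators=(", ", ": "))

    def encode_float(self, value: float) -> str:
        return f"{value:.{self.float_decimals}f}"


def _record_row(record: DatasetRecord, dialect: CsvDialect) -> list:
    cells = {
        "smiles": record.smiles,
        "chebi": dialect.encode_list(record.chebi),
        "num_heavy_atoms": str(record.num_heavy_atoms),
        "exact_mol_wt": dialect.encode_float(record.exact_mol_wt),
        "core_superstructure_smiles": dialect.encode_list(
            record.core_superstructure_smiles
        ),
        "core_superstructure_pubchem_cid": dialect.encode_list(
            [list(cids) for cids in record.core_superstructure_pubchem_cid]
        ),
        "rgroup_extended_smiles": dialect.encode_list(record.rgroup_extended_smiles),
        "rgroup_extended_pubchem_cid": dialect.encode_list(
            [list(cids) for cids in record.rgroup_extended_pubchem_cid]
        ),
    }
    return [cells[name] for name in dialect.column_order]


def write_dataset(
    records: List[DatasetRecord], path, dialect: CsvDialect = CsvDialect()
) -> str:
    """Write records to ``path`` and return the file's SHA-256 hex digest.

    A ``.gz`` suffix selects gzip compression (with a zeroed mtime so equal
    records give byte-identical files across runs).
    """
    buffer = io.StringIO(newline="")
    writer = csv.writer(buffer, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
    writer.writerow(dialect.column_order)
    for record in records:
        writer.writerow(_record_row(record, dialect))
    payload = buffer.getvalue().encode("utf-8")

    path = str(path)
    if path.endswith(".gz"):
        raw = io.BytesIO()
        with gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as gz:
            gz.write(payload)
        data = raw.getvalue()
    else:
        data = payload
    with open(path, "wb") as handle:
        handle.write(data)
    return hashlib.sha256(data).hexdigest()


def _decode_list(cell: str):
    cell = cell.strip()
    if not cell:
        return []
    try:
        return json.loads(cell)
    except json.JSONDecodeError:
        pass
    try:
        return ast.literal_eval(cell)
    except (ValueError, SyntaxError) as exc:
        raise ValueError(f"cannot decode list cell {cell!r}") from exc


def read_dataset(path, dialect: CsvDialect = CsvDialect()) -> List[DatasetRecord]:
    """Read a dataset file back into records (inverse of :func:`write_dataset`)."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt", encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise DatasetSchemaError(missing=dialect.column_order, extra=())
        expected = set(dialect.column_order)
        got = set(header)
        if got != expected or len(header) != len(dialect.column_order):
            raise DatasetSchemaError(
                missing=sorted(expected - got), extra=sorted(got - expected)
            )
        index = {name: header.index(name) for name in dialect.column_order}

        records = []
        for row_idx, row in enumerate(reader):
            records.append(_decode_row(row, row_idx, index))
    return records


def _decode_row(row, row_idx, index) -> DatasetRecord:
    def cell(name):
        return row[index[name]]

    def lists(name):
        try:
            value = _decode_list(cell(name))
        except ValueError as exc:
            raise DatasetRowError(row_idx, name, str(exc)) from exc
        if not isinstance(value, list):
            raise DatasetRowError(row_idx, name, "not a list")
        return value

    try:
        heavy = int(cell("num_heavy_atoms"))
    except ValueError as exc:
        raise DatasetRowError(
            row_idx, "num_heavy_atoms", f"not an integer: {cell('num_heavy_atoms')!r}"
        ) from exc
    try:
        wt = float(cell("exact_mol_wt"))
    except ValueError as exc:
        raise DatasetRowError(
            row_idx, "exact_mol_wt", f"not a float: {cell('exact_mol_wt')!r}"
        ) from exc

    return DatasetRecord(
        smiles=cell("smiles"),
        chebi=tuple(str(x) for x in lists("chebi")),
        num_heavy_atoms=heavy,
        exact_mol_wt=wt,
        core_superstructure_smiles=tuple(lists("core_superstructure_smiles")),
        core_superstructure_pubchem_cid=tuple(
            tuple(int(c) for c in cids)
            for cids in lists("core_superstructure_pubchem_cid")
        ),
        rgroup_extended_smiles=tuple(lists("rgroup_extended_smiles")),
        rgroup_extended_pubchem_cid=tuple(
            tuple(int(c) for c in cids)
            for cids in lists("rgroup_extended_pubchem_cid")
        ),
    )


def records_equal(a: DatasetRecord, b: DatasetRecord, wt_tol: float = 1e-4) -> bool:
    """Structural equality with a mass tolerance matching the 5-dp writer."""
    return (
        a.smiles == b.smiles
        and a.chebi == b.chebi
        and a.num_heavy_atoms == b.num_heavy_atoms
        and abs(a.exact_mol_wt - b.exact_mol_wt) <= wt_tol
        and a.core_superstructure_smiles == b.core_superstructure_smiles
        and a.core_superstructure_pubchem_cid == b.core_superstructure_pubchem_cid
        and a.rgroup_extended_smiles == b.rgroup_extended_smiles
        and a.rgroup_extended_pubchem_cid == b.rgroup_extended_pubchem_cid
    )
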