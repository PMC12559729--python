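"""Candidate compound library: ingestion, validation, dedup and weight queries.

The library stands in for a PubChem snapshot: records are (CID, structure)
pairs read from SMILES/TSV, InChI/TSV or SDF. Ingestion validates each
structure (parse + InChI round trip), applies the element policy, and
deduplicates on the standard InChI string, merging the identifier lists of
structurally identical records. Multi-entity records (dot-separated SMILES)
are kept whole at ingest; :func:`split_components` disaggregates them while
preserving provenance to the composite entry's identifiers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator, Optional, Tuple

from rdkit import Chem

from .errors import IdentifierCollisionError, MoleculeParseError
from .molecules import (
    ElementPolicy,
    canonical_smiles,
    element_set,
    exact_molecular_weight,
    parse_molecule,
    passes_element_policy,
    to_inchi,
)


@dataclass(frozen=True)
class CandidateCompound:
    """A fully defined library molecule with identifier provenance.

    ``cids`` collects every identifier whose record reduced to this InChI.
    """

    cids: tuple
    inchi: str
    smiles: str
    mol_wt: float
    element_set: frozenset
    n_components: int
    mol: Chem.Mol = field(repr=False, compare=False, default=None)


@dataclass(frozen=True)
class ComponentRecord:
    """One connected component of a (possibly composite) library entry."""

    parent_cids: tuple
    smiles: str
    mol_wt: float
    mol: Chem.Mol = field(repr=False, compare=False, default=None)


@dataclass
class IngestReport:
    """Counts describing one ingestion pass."""

    total_records: int = 0
    stored: int = 0
    merged: int = 0
    rejected_parse: int = 0
    rejected_policy: int = 0
    rejected_wildcard: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


class Store:
    """In-memory candidate index keyed by standard InChI.

    Exposes deterministic iteration in ascending (mol_wt, smiles) order and
    a strict weight-range query. The interface mirrors what a relational
    backing table would provide; at desk scale an in-memory dict suffices.
    """

    def __init__(self):
        self._by_inchi: dict = {}
        self._cid_to_inchi: dict = {}

    def __len__(self) -> int:
        return len(self._by_inchi)

    def __iter__(self) -> Iterator[CandidateCompound]:
        return iter(self.compounds())

    def add(self, compound: CandidateCompound) -> None:
        for cid in compound.cids:
            known = self._cid_to_inchi.get(cid)
            if known is not None and known != compound.inchi:
                raise IdentifierCollisionError(
                    f"identifier {cid} maps to two structures: "
                    f"{known!r} vs {compound.inchi!r}"
                )
        existing = self._by_inchi.get(compound.inchi)
        if existing is not None:
            merged = tuple(sorted(set(existing.cids) | set(compound.cids)))
            compound = CandidateCompound(
                cids=merged,
                inchi=existing.inchi,
                smiles=existing.smiles,
                mol_wt=existing.mol_wt,
                element_set=existing.element_set,
                n_components=existing.n_components,
                mol=existing.mol,
            )
        self._by_inchi[compound.inchi] = compound
        for cid in compound.cids:
            self._cid_to_inchi[cid] = compound.inchi

    def get_by_inchi(self, inchi: str) -> Optional[CandidateCompound]:
        return self._by_inchi.get(inchi)

    def compounds(self) -> list:
        return sorted(self._by_inchi.values(), key=lambda c: (c.mol_wt, c.smiles))

    def query_heavier_than(self, threshold: float) -> Iterator[CandidateCompound]:
        """Compounds with monoisotopic mass strictly greater than ``threshold``."""
        for compound in self.compounds():
            if compound.mol_wt > threshold:
                yield compound


def _build_compound(cid: int, text: str) -> CandidateCompound:
    mol = parse_molecule(text)
    if any(a.GetAtomicNum() == 0 for a in mol.GetAtoms()):
        raise MoleculeParseError(text, "candidate contains wildcard atoms")
    inchi = to_inchi(mol)
    if inchi is None:
        raise MoleculeParseError(text, "InChI validation failed")
    return CandidateCompound(
        cids=(int(cid),),
        inchi=inchi,
        smiles=canonical_smiles(mol),
        mol_wt=exact_molecular_weight(mol),
        element_set=element_set(mol),
        n_components=len(Chem.GetMolFrags(mol)),
        mol=mol,
    )


def ingest_library(
    records: Iterable[Tuple[int, str]], policy: ElementPolicy = ElementPolicy()
) -> Tuple[Store, IngestReport]:
    """Validate, filter and deduplicate (cid, structure-text) records.

    Records failing parse/InChI validation or the element policy are counted
    in the report, not stored. Structurally identical records (same standard
    InChI) are merged into one compound with a combined cid list. A cid seen
    with two different structures is a hard identifier collision.
    """
    store = Store()
    report = IngestReport()
    for cid, text in records:
        report.total_records += 1
        try:
            compound = _build_compound(cid, text)
        except MoleculeParseError as exc:
            if "wildcard" in exc.reason:
                report.rejected_wildcard += 1
            else:
                report.rejected_parse += 1
            continue
        if not passes_element_policy(compound.mol, policy):
            report.rejected_policy += 1
            continue
        before = len(store)
        store.add(compound)
        if len(store) == before:
            report.merged += 1
    report.stored = len(store)
    return store, report


def split_components(compound: CandidateCompound) -> list:
    """One :class:`ComponentRecord` per connected component.

    Each record carries the composite entry's full cid list as provenance.
    A single-component compound yields one record identical in structure.
    """
    frags = Chem.GetMolFrags(compound.mol, asMols=True, sanitizeFrags=True)
    return [
        ComponentRecord(
            parent_cids=compound.cids,
            smiles=canonical_smiles(frag),
            mol_wt=exact_molecular_weight(frag),
            mol=frag,
        )
        for frag in frags
    ]


# ---------------------------------------------------------------------------
# Readers


def read_smiles_tsv(path) -> Iterator[Tuple[int, str]]:
    """Yield (cid, smiles) from a two-column cid<TAB>smiles file."""
    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            cid, smiles = line.split("\t", 1)
            yield int(cid), smiles


read_inchi_tsv = read_smiles_tsv  # identical layout, InChI in the second column


def read_sdf(path, id_property: str = "PUBCHEM_COMPOUND_CID") -> Iterator[Tuple[int, str]]:
    """Yield (cid, smiles) from a V2000 SDF.

    The identifier is taken from ``id_property`` when present, falling back
    to the molecule title line.
    """
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=False)
    for mol in supplier:
        if mol is None:
            continue
        if mol.HasProp(id_property):
            cid = int(mol.GetProp(id_property))
        else:
            cid = int(mol.GetProp("_Name"))
        yield cid, Chem.MolToSmiles(mol)
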