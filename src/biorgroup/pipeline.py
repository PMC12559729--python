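"""End-to-end orchestration: query file → filters → expansion → records.

The pipeline reads an identifier<TAB>SMILES query file (the layout of
Rhea's ``rhea-chebi-smiles.tsv``), merges identifiers sharing a SMILES
string, applies the selection filters with full accounting (R-group
presence first, then the six-heavy-atom rule, then the element policy),
expands every retained query against the candidate store, and assembles
one eight-column dataset record per molecule.

Two emission modes are supported: ``full`` (one record per unique molecule,
R-group-free ones carrying empty match lists — mirroring the published
dataset layout) and ``expanded-only`` (records for retained queries only).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

from .compound_store import CandidateCompound, Store
from .errors import MoleculeParseError, QueryFileError
from .molecules import ElementPolicy, GenericMolecule
from .rgroup_matcher import ExpansionResult, MatchConfig, expand_query


@dataclass
class FilterReport:
    """Accounting of the query-selection filters.

    Invariants: ``with_rgroup + no_rgroup == unique_after_merge`` and
    ``retained_queries == with_rgroup - excluded_heavy_atoms -
    excluded_elements``; ``retention_fraction`` is the retained share of
    the R-group-bearing molecules.
    """

    total_records: int = 0
    unique_after_merge: int = 0
    no_rgroup: int = 0
    with_rgroup: int = 0
    excluded_heavy_atoms: int = 0
    excluded_elements: int = 0
    retained_queries: int = 0

    @property
    def retention_fraction(self) -> float:
        if self.with_rgroup == 0:
            return 0.0
        return self.retained_queries / self.with_rgroup

    def to_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in (
                "total_records",
                "unique_after_merge",
                "no_rgroup",
                "with_rgroup",
                "excluded_heavy_atoms",
                "excluded_elements",
                "retained_queries",
            )
        }
        out["retention_fraction"] = self.retention_fraction
        return out


@dataclass(frozen=True)
class DatasetRecord:
    """One output row: descriptors plus the two aligned match-list pairs."""

    smiles: str
    chebi: tuple
    num_heavy_atoms: int
    exact_mol_wt: float
    core_superstructure_smiles: tuple = ()
    core_superstructure_pubchem_cid: tuple = ()
    rgroup_extended_smiles: tuple = ()
    rgroup_extended_pubchem_cid: tuple = ()

    def __post_init__(self):
        if len(self.core_superstructure_smiles) != len(
            self.core_superstructure_pubchem_cid
        ) or len(self.rgroup_extended_smiles) != len(self.rgroup_extended_pubchem_cid):
            raise ValueError("cid lists must align index-wise with smiles lists")


@dataclass(frozen=True)
class PipelineConfig:
    match: MatchConfig = MatchConfig()
    policy: ElementPolicy = ElementPolicy()
    min_heavy: int = 6
    mode: str = "full"  # "full" | "expanded-only"
    merge_canonical: bool = False

    def __post_init__(self):
        if self.mode not in ("full", "expanded-only"):
            raise ValueError(f"unknown emission mode {self.mode!r}")


@dataclass
class PipelineResult:
    records: List[DatasetRecord]
    report: FilterReport
    timeout_log: List[tuple]
    manifest: dict


def load_query_file(path) -> Tuple[List[Tuple[str, str]], List[Tuple[int, str]]]:
    """Read identifier<TAB>SMILES pairs, in file order.

    Returns (records, line_errors); a malformed line (field count != 2) is
    reported with its 1-based line number and the remaining lines are kept.
    """
    records: List[Tuple[str, str]] = []
    errors: List[Tuple[int, str]] = []
    try:
        handle = open(path, "r", encoding="utf-8")
    except OSError as exc:
        raise QueryFileError(f"cannot read query file {path}: {exc}") from exc
    with handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                errors.append((lineno, line))
                continue
            records.append((fields[0], fields[1]))
    return records, errors


def merge_identical_smiles(
    records, canonical: bool = False
) -> Tuple[List[GenericMolecule], int, List[Tuple[str, str]]]:
    """One molecule per distinct SMILES string, identifiers collected.

    The merge key is the verbatim SMILES string by default (set
    ``canonical=True`` to merge on canonical form instead). Unparsable
    SMILES are returned separately, not silently dropped. Returns
    (molecules, n_merged_identifiers, parse_failures).
    """
    groups: dict = {}
    order: list = []
    failures: List[Tuple[str, str]] = []
    keyed: dict = {}
    for ident, smiles in records:
        if canonical:
            key = keyed.get(smiles)
            if key is None:
                try:
                    key = GenericMolecule.from_smiles(smiles, []).smiles
                except MoleculeParseError:
                    failures.append((ident, smiles))
                    continue
                keyed[smiles] = key
        else:
            key = smiles
        if key not in groups:
            groups[key] = (smiles, [])
            order.append(key)
        groups[key][1].append(ident)

    molecules: List[GenericMolecule] = []
    merged = 0
    for key in order:
        smiles, idents = groups[key]
        unique_ids = list(dict.fromkeys(idents))
        merged += len(idents) - 1
        try:
            molecules.append(GenericMolecule.from_smiles(smiles, unique_ids))
        except MoleculeParseError:
            failures.extend((i, smiles) for i in unique_ids)
    return molecules, merged, failures


def select_queries(
    molecules: List[GenericMolecule],
    policy: ElementPolicy = ElementPolicy(),
    min_heavy: int = 6,
) -> Tuple[List[GenericMolecule], FilterReport]:
    """Apply the selection filters with the reported exclusion order.

    A molecule is a retained query iff it has at least one R position, at
    least ``min_heavy`` heavy atoms, and only allowed elements. Exclusions
    are accounted in that sequence, so a molecule failing several filters
    is counted once, under the first.
    """
    from .molecules import passes_element_policy

    report = FilterReport(unique_after_merge=len(molecules))
    queries: List[GenericMolecule] = []
    for mol in molecules:
        if not mol.is_query:
            report.no_rgroup += 1
            continue
        report.with_rgroup += 1
        if mol.num_heavy_atoms < min_heavy:
            report.excluded_heavy_atoms += 1
            continue
        if not passes_element_policy(mol.mol, policy):
            report.excluded_elements += 1
            continue
        queries.append(mol)
    report.retained_queries = len(queries)
    return queries, report


def build_record(
    molecule: GenericMolecule, expansion: Optional[ExpansionResult]
) -> DatasetRecord:
    if expansion is None:
        return DatasetRecord(
            smiles=molecule.smiles,
            chebi=molecule.source_ids,
            num_heavy_atoms=molecule.num_heavy_atoms,
            exact_mol_wt=molecule.exact_mol_wt,
        )
    return DatasetRecord(
        smiles=molecule.smiles,
        chebi=molecule.source_ids,
        num_heavy_atoms=molecule.num_heavy_atoms,
        exact_mol_wt=molecule.exact_mol_wt,
        core_superstructure_smiles=tuple(e.smiles for e in expansion.superstructure),
        core_superstructure_pubchem_cid=tuple(
            e.cids for e in expansion.superstructure
        ),
        rgroup_extended_smiles=tuple(e.smiles for e in expansion.rgroup_extended),
        rgroup_extended_pubchem_cid=tuple(e.cids for e in expansion.rgroup_extended),
    )


def run_pipeline(
    query_path,
    store: Store,
    config: PipelineConfig = PipelineConfig(),
    clock: Optional[Callable[[], float]] = None,
    cost_model: Optional[Callable[[GenericMolecule, CandidateCompound], float]] = None,
) -> PipelineResult:
    """Full run: load, merge, filter, expand, assemble records.

    Records are ordered by the first appearance of their SMILES in the
    query file. In ``full`` mode every unique molecule gets a record
    (non-queries with four empty lists); in ``expanded-only`` mode only
    retained queries do.
    """
    t0 = time.monotonic()
    records_in, line_errors = load_query_file(query_path)
    molecules, merged, parse_failures = merge_identical_smiles(
        records_in, canonical=config.merge_canonical
    )
    queries, report = select_queries(molecules, config.policy, config.min_heavy)
    report.total_records = len(records_in)
    retained = {id(m) for m in queries}

    out: List[DatasetRecord] = []
    timeout_log: List[tuple] = []
    for mol in molecules:
        if id(mol) in retained:
            expansion = expand_query(
                mol, store, config.match, clock=clock, cost_model=cost_model
            )
            timeout_log.extend(expansion.timed_out)
            out.append(build_record(mol, expansion))
        elif config.mode == "full":
            out.append(build_record(mol, None))

    with open(query_path, "rb") as handle:
        digest = hashlib.sha256(handle.read()).hexdigest()
    manifest = {
        "config": {
            "match": {
                "timeout_seconds": config.match.timeout_seconds,
                "allow_hydrogen_substituent": config.match.allow_hydrogen_substituent,
                "require_all_r_substituted": config.match.require_all_r_substituted,
                "match_defined_stereo": config.match.match_defined_stereo,
            },
            "allowed_elements": sorted(config.policy.allowed_elements),
            "min_heavy": config.min_heavy,
            "mode": config.mode,
            "merge_canonical": config.merge_canonical,
        },
        "input_sha256": digest,
        "n_library_compounds": len(store),
        "n_line_errors": len(line_errors),
        "n_parse_failures": len(parse_failures),
        "n_merged_identifiers": merged,
        "filter_report": report.to_dict(),
        "elapsed_seconds": time.monotonic() - t0,
    }
    return PipelineResult(
        records=out, report=report, timeout_log=timeout_log, manifest=manifest
    )


def write_manifest(result: PipelineResult, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(result.manifest, handle, indent=2, sort_keys=True)
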