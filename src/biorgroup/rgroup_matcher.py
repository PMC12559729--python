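"""Core-structure matching and R-group-extension classification.

This is the heart of the pipeline. For a generic query (a core plus one or
more wildcard R positions) and a fully defined candidate, decide:

1. does the candidate *contain* the query's core — an injective, adjacency-
   preserving embedding of the core atoms that preserves element, formal
   charge, isotope, bond order, and every stereo descriptor the query
   defines (query-undefined stereo matches anything); and
2. if so, do *all* additional atoms sit exclusively at the R positions, one
   connected substituent group per position (``RGROUP_EXTENDED``), or are
   there additions elsewhere (``CORE_SUPERSTRUCTURE``)?

Classification is existential over embeddings: a candidate is
``RGROUP_EXTENDED`` if *any* valid embedding achieves empty leftovers.
Candidates are matched with explicit hydrogens so that a bare R position can
carry the hydrogen-only substituent group.

At library scale, :func:`expand_query` runs the three-step procedure:
weight-prefiltered matching with a per-pair timeout, disaggregation of
multi-entity candidates with provenance to the composite identifiers, and
final classification of every core match.
"""

from __future__ import annotations

import enum
import time
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

from rdkit import Chem

from .compound_store import CandidateCompound, Store, split_components
from .errors import StructureError
from .molecules import GenericMolecule, canonical_smiles, to_inchi

_CHI_TETRA = (
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
)

_DEFINED_BOND_STEREO = (
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
)


class MatchClass(enum.Enum):
    """Relationship of a core-matching candidate to the query."""

    CORE_SUPERSTRUCTURE = "core_superstructure"
    RGROUP_EXTENDED = "rgroup_extended"


class Timeout:
    """Sentinel returned when a (query, candidate) pair exceeded its budget."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):  # pragma: no cover
        return "TIMEOUT"


TIMEOUT = Timeout()


@dataclass(frozen=True)
class MatchConfig:
    """Matching knobs; defaults mirror the production pipeline.

    ``timeout_seconds``
        wall-clock budget per (query, candidate) pair.
    ``allow_hydrogen_substituent``
        whether the hydrogen-only group counts as a valid R substituent.
    ``require_all_r_substituted``
        whether every R position must receive a substituent group for the
        extended classification.
    ``match_defined_stereo``
        enforce query-defined chiral-center parities and double-bond
        configurations (enhanced stereo groups are ignored entirely).
    """

    timeout_seconds: float = 10.0
    allow_hydrogen_substituent: bool = True
    require_all_r_substituted: bool = True
    match_defined_stereo: bool = True

    def __post_init__(self):
        if self.timeout_seconds <= 0:
            raise ValueError("timeout_seconds must be positive")


@dataclass(frozen=True)
class CoreMatch:
    """One embedding of the query core into a candidate, analysed.

    ``atom_map`` maps every query atom index (wildcards included) to a
    candidate atom index in the hydrogen-explicit candidate.
    ``substituent_assignment`` maps R labels to the connected candidate atom
    set hanging off that position; ``hydrogen_labels`` flags the labels whose
    group is the single hydrogen. ``leftover_atoms`` are candidate atoms in
    neither the core image nor any valid substituent group;
    ``extra_core_bonds`` counts candidate bonds between core-image atoms
    that are not images of query bonds (an addition not at an R position).
    """

    atom_map: Tuple[Tuple[int, int], ...]
    substituent_assignment: Tuple[Tuple[int, frozenset], ...]
    hydrogen_labels: frozenset
    leftover_atoms: frozenset
    extra_core_bonds: int

    def substituents(self) -> Dict[int, frozenset]:
        return dict(self.substituent_assignment)


@dataclass(frozen=True)
class MatchResult:
    """Record of one (query, candidate) matching attempt."""

    query_smiles: str
    candidate_smiles: str
    match_class: Optional[MatchClass]
    cids: tuple
    timed_out: bool
    elapsed: float


@dataclass(frozen=True)
class MatchEntry:
    """One deduplicated matched structure in an expansion result."""

    smiles: str
    cids: tuple
    mol_wt: float
    match_class: MatchClass


@dataclass
class ExpansionResult:
    """Output of :func:`expand_query` for a single query."""

    superstructure: List[MatchEntry] = field(default_factory=list)
    rgroup_extended: List[MatchEntry] = field(default_factory=list)
    timed_out: List[tuple] = field(default_factory=list)
    n_match_calls: int = 0


# ---------------------------------------------------------------------------
# Query preparation and embedding analysis


def prepare_core_query(query_mol: Chem.Mol) -> Chem.Mol:
    """Turn a wildcard-bearing molecule into an RDKit substructure query.

    Wildcards become match-any query atoms; their isotope labels are cleared
    (an R label is bookkeeping, not a matching constraint).
    """
    work = Chem.Mol(query_mol)
    for atom in work.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetIsotope(0)
    params = Chem.AdjustQueryParameters.NoAdjustments()
    params.makeDummiesQueries = True
    return Chem.AdjustQueryProperties(work, params)


def candidate_with_hs(candidate: Chem.Mol) -> Chem.Mol:
    if any(a.GetAtomicNum() == 0 for a in candidate.GetAtoms()):
        raise StructureError("candidate molecule contains wildcard atoms")
    return Chem.AddHs(candidate)


def _postcheck_embedding(
    query_mol: Chem.Mol,
    cand_h: Chem.Mol,
    mapping: tuple,
    check_stereo: bool,
) -> bool:
    """Exactness checks RDKit's default matcher does not enforce.

    Formal charge and isotope must match exactly on core atoms, and every
    query-defined stereo descriptor must be *defined* on the candidate
    (parity equality itself is enforced by chirality-aware matching).
    """
    for q_atom in query_mol.GetAtoms():
        if q_atom.GetAtomicNum() == 0:
            continue
        c_atom = cand_h.GetAtomWithIdx(mapping[q_atom.GetIdx()])
        if q_atom.GetFormalCharge() != c_atom.GetFormalCharge():
            return False
        if q_atom.GetIsotope() != c_atom.GetIsotope():
            return False
        if (
            check_stereo
            and q_atom.GetChiralTag() in _CHI_TETRA
            and c_atom.GetChiralTag() not in _CHI_TETRA
        ):
            return False
    if check_stereo:
        for q_bond in query_mol.GetBonds():
            if q_bond.GetStereo() not in _DEFINED_BOND_STEREO:
                continue
            c_bond = cand_h.GetBondBetweenAtoms(
                mapping[q_bond.GetBeginAtomIdx()], mapping[q_bond.GetEndAtomIdx()]
            )
            if c_bond is None or c_bond.GetStereo() not in _DEFINED_BOND_STEREO:
                return False
    return True


def analyze_embedding(
    query: GenericMolecule, cand_h: Chem.Mol, mapping: tuple
) -> CoreMatch:
    """Partition the candidate into core image, substituent groups, leftovers.

    Hydrogens on core-image atoms are absorbed into the core (an extra H is
    never an addition), except when an H is itself a wildcard's image — that
    is the hydrogen-only substituent group. A non-core component qualifies as
    a substituent iff it contains exactly one wildcard image and touches the
    core only through that wildcard's anchor image; anything else is leftover.
    """
    query_mol = query.mol
    wildcard_by_image = {}
    anchor_image = {}
    for pos in query.r_positions:
        wildcard_by_image[mapping[pos.wildcard_index]] = pos
        anchor_image[pos.label] = mapping[pos.anchor_index]
    core_image = {
        mapping[a.GetIdx()]
        for a in query_mol.GetAtoms()
        if a.GetAtomicNum() != 0
    }

    absorbed = set()
    for idx in range(cand_h.GetNumAtoms()):
        atom = cand_h.GetAtomWithIdx(idx)
        if (
            atom.GetAtomicNum() == 1
            and idx not in core_image
            and idx not in wildcard_by_image
            and any(n.GetIdx() in core_image for n in atom.GetNeighbors())
        ):
            absorbed.add(idx)

    outside = [
        i
        for i in range(cand_h.GetNumAtoms())
        if i not in core_image and i not in absorbed
    ]
    outside_set = set(outside)

    # connected components of the candidate graph restricted to `outside`
    components = []
    seen = set()
    for start in outside:
        if start in seen:
            continue
        comp = set()
        stack = [start]
        while stack:
            cur = stack.pop()
            if cur in comp:
                continue
            comp.add(cur)
            for nbr in cand_h.GetAtomWithIdx(cur).GetNeighbors():
                j = nbr.GetIdx()
                if j in outside_set and j not in comp:
                    stack.append(j)
        seen |= comp
        components.append(comp)

    substituents = {}
    hydrogen_labels = set()
    leftover = set()
    for comp in components:
        wildcards_here = [wildcard_by_image[i] for i in comp if i in wildcard_by_image]
        if len(wildcards_here) != 1:
            leftover |= comp
            continue
        pos = wildcards_here[0]
        anchor_img = anchor_image[pos.label]
        clean = True
        for i in comp:
            for nbr in cand_h.GetAtomWithIdx(i).GetNeighbors():
                j = nbr.GetIdx()
                if (j in core_image or j in absorbed) and j != anchor_img:
                    clean = False
        if not clean:
            leftover |= comp
            continue
        substituents[pos.label] = frozenset(comp)
        if len(comp) == 1 and cand_h.GetAtomWithIdx(next(iter(comp))).GetAtomicNum() == 1:
            hydrogen_labels.add(pos.label)

    query_bond_images = set()
    for bond in query_mol.GetBonds():
        a, b = mapping[bond.GetBeginAtomIdx()], mapping[bond.GetEndAtomIdx()]
        query_bond_images.add(frozenset((a, b)))
    extra_core_bonds = 0
    for bond in cand_h.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if a in core_image and b in core_image:
            if frozenset((a, b)) not in query_bond_images:
                extra_core_bonds += 1

    return CoreMatch(
        atom_map=tuple((i, mapping[i]) for i in range(query_mol.GetNumAtoms())),
        substituent_assignment=tuple(sorted(substituents.items())),
        hydrogen_labels=frozenset(hydrogen_labels),
        leftover_atoms=frozenset(leftover),
        extra_core_bonds=extra_core_bonds,
    )


def classify_match(match: CoreMatch, config: MatchConfig = MatchConfig()) -> MatchClass:
    """``RGROUP_EXTENDED`` iff every addition sits exactly at an R position.

    Requires empty leftovers, no extra core-core bonds, and one substituent
    group per R position, the hydrogen-only group being admissible per
    configuration. Anything else containing the core is a superstructure.
    """
    if match.leftover_atoms or match.extra_core_bonds:
        return MatchClass.CORE_SUPERSTRUCTURE
    assigned = dict(match.substituent_assignment)
    n_positions = len({lbl for lbl, _ in match.substituent_assignment})
    # every wildcard maps somewhere; a disqualified group would be leftover
    for label in assigned:
        if label in match.hydrogen_labels:
            if config.allow_hydrogen_substituent:
                continue
            if not config.require_all_r_substituted:
                continue  # H read as "unsubstituted", tolerated when not all R required
            return MatchClass.CORE_SUPERSTRUCTURE
    if n_positions == 0:
        return MatchClass.CORE_SUPERSTRUCTURE
    return MatchClass.RGROUP_EXTENDED


# ---------------------------------------------------------------------------
# Per-pair matching


def _iter_embeddings(qmol: Chem.Mol, cand_h: Chem.Mol, use_chirality: bool):
    params = Chem.SubstructMatchParameters()
    params.useChirality = use_chirality
    params.uniquify = False
    params.maxMatches = 100000
    return cand_h.GetSubstructMatches(qmol, params)


def match_core(
    query: GenericMolecule,
    candidate: Chem.Mol,
    config: MatchConfig = MatchConfig(),
    clock: Optional[Callable[[], float]] = None,
):
    """Find the best core embedding of ``query`` in ``candidate``.

    Returns a :class:`CoreMatch` (preferring an embedding that classifies as
    ``RGROUP_EXTENDED``), ``None`` when no valid embedding exists, or the
    :data:`TIMEOUT` sentinel when the wall-clock budget is exceeded. The
    candidate must be fully defined (wildcards are a contract violation).
    """
    if not query.r_positions:
        raise StructureError("query has no R positions")
    clock = clock or time.monotonic
    deadline = clock() + config.timeout_seconds
    cand_h = candidate_with_hs(candidate)
    qmol = prepare_core_query(query.mol)

    if clock() > deadline:
        return TIMEOUT
    embeddings = _iter_embeddings(qmol, cand_h, config.match_defined_stereo)
    best = None
    for mapping in embeddings:
        if clock() > deadline:
            return TIMEOUT
        if not _postcheck_embedding(
            query.mol, cand_h, mapping, config.match_defined_stereo
        ):
            continue
        match = analyze_embedding(query, cand_h, mapping)
        if classify_match(match, config) is MatchClass.RGROUP_EXTENDED:
            return match
        if best is None:
            best = match
    return best


def classify_pair(
    query: GenericMolecule,
    candidate: Chem.Mol,
    config: MatchConfig = MatchConfig(),
    clock: Optional[Callable[[], float]] = None,
):
    """Convenience: match then classify. Returns MatchClass, None or TIMEOUT."""
    match = match_core(query, candidate, config, clock)
    if match is TIMEOUT or match is None:
        return match
    return classify_match(match, config)


# ---------------------------------------------------------------------------
# Library-scale expansion (the three-step procedure)


def expand_query(
    query: GenericMolecule,
    store: Store,
    config: MatchConfig = MatchConfig(),
    clock: Optional[Callable[[], float]] = None,
    cost_model: Optional[Callable[[GenericMolecule, CandidateCompound], float]] = None,
) -> ExpansionResult:
    """Expand one query against the store.

    Step 1 matches every candidate whose monoisotopic mass strictly exceeds
    the query's, under the per-pair timeout. Step 2 disaggregates matched
    multi-entity candidates and re-matches each component heavier than the
    query, attributing the composite entry's identifiers. Step 3 classifies
    every core match; the extended list is the subset of the superstructure
    list whose additions sit exclusively at R positions.

    ``cost_model``, when given, replaces wall-clock timing with a simulated
    per-pair cost in seconds (a pair times out iff its cost exceeds the
    configured budget) so that timeout behaviour is exactly reproducible.
    """
    result = ExpansionResult()
    entries: Dict[str, dict] = {}

    def attempt(mol: Chem.Mol, compound_for_cost: CandidateCompound):
        if cost_model is not None:
            if cost_model(query, compound_for_cost) > config.timeout_seconds:
                return TIMEOUT
            result.n_match_calls += 1
            relaxed = MatchConfig(
                timeout_seconds=float("inf"),
                allow_hydrogen_substituent=config.allow_hydrogen_substituent,
                require_all_r_substituted=config.require_all_r_substituted,
                match_defined_stereo=config.match_defined_stereo,
            )
            return match_core(query, mol, relaxed, clock=lambda: 0.0)
        result.n_match_calls += 1
        return match_core(query, mol, config, clock)

    def record(mol: Chem.Mol, cids: tuple, match: CoreMatch):
        inchi = to_inchi(mol)
        if inchi is None:  # pragma: no cover - candidates already validated
            return
        cls = classify_match(match, config)
        entry = entries.setdefault(
            inchi,
            {
                "smiles": canonical_smiles(mol),
                "mol_wt": _mol_wt(mol),
                "cids": set(),
                "class": cls,
            },
        )
        entry["cids"].update(cids)
        if cls is MatchClass.RGROUP_EXTENDED:
            entry["class"] = cls

    for compound in store.query_heavier_than(query.exact_mol_wt):
        outcome = attempt(compound.mol, compound)
        if outcome is TIMEOUT:
            result.timed_out.append(compound.cids)
            continue
        if outcome is None:
            continue
        record(compound.mol, compound.cids, outcome)
        if compound.n_components > 1:
            for component in split_components(compound):
                if component.mol_wt <= query.exact_mol_wt:
                    continue
                sub_outcome = attempt(component.mol, compound)
                if sub_outcome is TIMEOUT:
                    result.timed_out.append(compound.cids)
                    continue
                if sub_outcome is not None:
                    record(component.mol, component.parent_cids, sub_outcome)

    ordered = sorted(entries.values(), key=lambda e: (e["mol_wt"], e["smiles"]))
    for entry in ordered:
        item = MatchEntry(
            smiles=entry["smiles"],
            cids=tuple(sorted(entry["cids"])),
            mol_wt=entry["mol_wt"],
            match_class=entry["class"],
        )
        result.superstructure.append(item)
        if entry["class"] is MatchClass.RGROUP_EXTENDED:
            result.rgroup_extended.append(item)
    return result


def _mol_wt(mol: Chem.Mol) -> float:
    from .molecules import exact_molecular_weight

    return exact_molecular_weight(mol)
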