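"""Exhaustive-embedding classification oracle for small instances.

Independent cross-check for the matcher: enumerates *all* injective,
adjacency-preserving embeddings of the query's atoms into the hydrogen-
explicit candidate with a generic subgraph-monomorphism search (VF2 via
networkx), checks stereo descriptors with explicit parity arithmetic, and
classifies by first principles. No RDKit substructure machinery is used.

The oracle refuses candidates above 20 heavy atoms: it exists to certify
desk-scale instances, not to run at library scale.
"""

from __future__ import annotations

from typing import Dict, Optional

import networkx as nx
from rdkit import Chem

from .errors import OracleSizeError
from .molecules import GenericMolecule, count_heavy_atoms
from .rgroup_matcher import MatchClass, MatchConfig

_CHI = (
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
)
_SAME_SIDE = (Chem.BondStereo.STEREOZ, Chem.BondStereo.STEREOCIS)
_DEFINED = _SAME_SIDE + (Chem.BondStereo.STEREOE, Chem.BondStereo.STEREOTRANS)


def _mol_graph(mol: Chem.Mol, wildcard_any: bool) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(
            atom.GetIdx(),
            z=atom.GetAtomicNum(),
            chg=atom.GetFormalCharge(),
            iso=atom.GetIsotope(),
            any=(wildcard_any and atom.GetAtomicNum() == 0),
        )
    for bond in mol.GetBonds():
        g.add_edge(
            bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), bt=int(bond.GetBondType())
        )
    return g


def _node_match(c_attrs, q_attrs) -> bool:
    if q_attrs["any"]:
        return True
    return (
        c_attrs["z"] == q_attrs["z"]
        and c_attrs["chg"] == q_attrs["chg"]
        and c_attrs["iso"] == q_attrs["iso"]
    )


def _edge_match(c_attrs, q_attrs) -> bool:
    return c_attrs["bt"] == q_attrs["bt"]


def _perm_parity(perm) -> int:
    seen = [False] * len(perm)
    parity = 0
    for i in range(len(perm)):
        if seen[i]:
            continue
        j, length = i, 0
        while not seen[j]:
            seen[j] = True
            j = perm[j]
            length += 1
        parity ^= (length - 1) & 1
    return parity


def _bond_order_neighbors(atom: Chem.Atom):
    return [b.GetOtherAtom(atom).GetIdx() for b in atom.GetBonds()]


def _tetra_ok(query_h, cand_h, n_query_atoms, q2c, q_idx) -> bool:
    qa = query_h.GetAtomWithIdx(q_idx)
    ca = cand_h.GetAtomWithIdx(q2c[q_idx])
    if ca.GetChiralTag() not in _CHI:
        return False
    q_nbrs = _bond_order_neighbors(qa)
    c_nbrs = _bond_order_neighbors(ca)
    if len(q_nbrs) != len(c_nbrs):
        return False
    images = []
    for qn in q_nbrs:
        images.append(q2c[qn] if qn < n_query_atoms else None)
    mapped = {i for i in images if i is not None}
    free = [c for c in c_nbrs if c not in mapped]
    if images.count(None) != len(free) or images.count(None) > 1:
        return False
    images = [free[0] if i is None else i for i in images]
    if set(images) != set(c_nbrs):
        return False
    perm = [c_nbrs.index(i) for i in images]
    same_tag = qa.GetChiralTag() == ca.GetChiralTag()
    return same_tag == (_perm_parity(perm) == 0)


def _double_bond_ok(query_mol, cand_h, q2c, q_bond) -> bool:
    cb = cand_h.GetBondBetweenAtoms(
        q2c[q_bond.GetBeginAtomIdx()], q2c[q_bond.GetEndAtomIdx()]
    )
    if cb is None or cb.GetStereo() not in _DEFINED:
        return False
    q_refs = list(q_bond.GetStereoAtoms())
    c_refs = list(cb.GetStereoAtoms())
    if len(q_refs) != 2 or len(c_refs) != 2:
        return False
    qb = q_bond.GetBeginAtomIdx()
    # align reference atoms end-by-end
    q_mol_begin_nbrs = [
        a.GetIdx() for a in query_mol.GetAtomWithIdx(qb).GetNeighbors()
    ]
    if q_refs[0] not in q_mol_begin_nbrs:
        q_refs = [q_refs[1], q_refs[0]]
    cb_begin = cb.GetBeginAtomIdx()
    c_begin_nbrs = [a.GetIdx() for a in cand_h.GetAtomWithIdx(cb_begin).GetNeighbors()]
    if c_refs[0] not in c_begin_nbrs:
        c_refs = [c_refs[1], c_refs[0]]
    if q2c[qb] != cb_begin:
        c_refs = [c_refs[1], c_refs[0]]
    flips = int(q2c[q_refs[0]] != c_refs[0]) + int(q2c[q_refs[1]] != c_refs[1])
    q_same = q_bond.GetStereo() in _SAME_SIDE
    c_same = cb.GetStereo() in _SAME_SIDE
    return q_same == (c_same ^ (flips % 2 == 1))


def _stereo_ok(query_mol, query_h, cand_h, q2c) -> bool:
    n_orig = query_mol.GetNumAtoms()
    for atom in query_mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            continue
        if atom.GetChiralTag() in _CHI:
            if not _tetra_ok(query_h, cand_h, n_orig, q2c, atom.GetIdx()):
                return False
    for bond in query_mol.GetBonds():
        if bond.GetStereo() in _DEFINED:
            if not _double_bond_ok(query_mol, cand_h, q2c, bond):
                return False
    return True


def _classify_embedding(
    query: GenericMolecule, cand_h: Chem.Mol, q2c: Dict[int, int], config: MatchConfig
) -> MatchClass:
    """Classify one embedding from first principles (fresh graph walk)."""
    adjacency = {
        a.GetIdx(): [n.GetIdx() for n in a.GetNeighbors()] for a in cand_h.GetAtoms()
    }
    is_h = {a.GetIdx(): a.GetAtomicNum() == 1 for a in cand_h.GetAtoms()}
    core = {
        q2c[a.GetIdx()] for a in query.mol.GetAtoms() if a.GetAtomicNum() != 0
    }
    wimg = {q2c[p.wildcard_index]: p for p in query.r_positions}
    aimg = {p.label: q2c[p.anchor_index] for p in query.r_positions}

    # extra candidate bonds inside the core image
    qbonds = {
        frozenset((q2c[b.GetBeginAtomIdx()], q2c[b.GetEndAtomIdx()]))
        for b in query.mol.GetBonds()
    }
    for a in core:
        for b in adjacency[a]:
            if b in core and a < b and frozenset((a, b)) not in qbonds:
                return MatchClass.CORE_SUPERSTRUCTURE

    absorbed = {
        i
        for i in adjacency
        if is_h[i]
        and i not in core
        and i not in wimg
        and any(n in core for n in adjacency[i])
    }
    outside = set(adjacency) - core - absorbed
    visited = set()
    for start in sorted(outside):
        if start in visited:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            cur = frontier.pop()
            for n in adjacency[cur]:
                if n in outside and n not in comp:
                    comp.add(n)
                    frontier.append(n)
        visited |= comp
        wcs = [wimg[i] for i in comp if i in wimg]
        if len(wcs) != 1:
            return MatchClass.CORE_SUPERSTRUCTURE
        anchor = aimg[wcs[0].label]
        for i in comp:
            for n in adjacency[i]:
                if (n in core or n in absorbed) and n != anchor:
                    return MatchClass.CORE_SUPERSTRUCTURE
        if len(comp) == 1 and is_h[next(iter(comp))]:
            permitted = (
                config.allow_hydrogen_substituent
                or not config.require_all_r_substituted
            )
            if not permitted:
                return MatchClass.CORE_SUPERSTRUCTURE
    return MatchClass.RGROUP_EXTENDED


def oracle_classify(
    query: GenericMolecule,
    candidate: Chem.Mol,
    config: MatchConfig = MatchConfig(),
    max_heavy_atoms: int = 20,
) -> Optional[MatchClass]:
    """Classify a (query, candidate) pair by exhaustive enumeration.

    Same contract as ``match_core`` + ``classify_match`` (existential over
    embeddings, no timeout): returns ``RGROUP_EXTENDED`` when any embedding
    puts every addition exclusively at R positions, ``CORE_SUPERSTRUCTURE``
    when the core embeds at all, else ``None``.
    """
    if count_heavy_atoms(candidate) > max_heavy_atoms:
        raise OracleSizeError(
            f"candidate has more than {max_heavy_atoms} heavy atoms"
        )
    cand_h = Chem.AddHs(candidate)
    query_h = Chem.AddHs(query.mol)
    gq = _mol_graph(query.mol, wildcard_any=True)
    gc = _mol_graph(cand_h, wildcard_any=False)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        gc, gq, node_match=_node_match, edge_match=_edge_match
    )
    best = None
    for c2q in matcher.subgraph_monomorphisms_iter():
        q2c = {q: c for c, q in c2q.items()}
        if config.match_defined_stereo and not _stereo_ok(
            query.mol, query_h, cand_h, q2c
        ):
            continue
        cls = _classify_embedding(query, cand_h, q2c, config)
        if cls is MatchClass.RGROUP_EXTENDED:
            return cls
        best = cls
    return best
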