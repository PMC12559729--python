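"""Molecule parsing, canonicalization and the query-selection predicates.

Generic molecules carry wildcard atoms (``*`` or ``[n*]``) marking R-group
positions: placeholders for unspecified substituents. This module parses
SMILES/InChI input into RDKit molecules, locates R positions, and implements
the descriptor predicates used to select query molecules: heavy-atom count,
monoisotopic weight, and the biological-element policy.

Conventions adopted throughout the package:

* wildcard atoms are *not* heavy atoms and contribute zero mass;
* ``exact_mol_wt`` is the monoisotopic mass;
* a single aromaticity perception (RDKit's default sanitization) is applied
  to every molecule, so SMILES dialect (aromatic vs Kekulé) never matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from rdkit import Chem, RDLogger
from rdkit.Chem.Descriptors import ExactMolWt

from .errors import MoleculeParseError, StructureError

RDLogger.DisableLog("rdApp.*")

#: Elements commonly found in living organisms; everything else is filtered out.
BIOLOGICAL_ELEMENTS = frozenset(
    {"H", "C", "N", "O", "Na", "Mg", "P", "S", "Cl", "K", "Ca"}
)


@dataclass(frozen=True)
class ElementPolicy:
    """Whitelist of element symbols a molecule may contain.

    Wildcard atoms are ignored by the predicate: an R position says nothing
    about the elements that may eventually substitute it.
    """

    allowed_elements: frozenset = BIOLOGICAL_ELEMENTS

    def __post_init__(self):
        object.__setattr__(self, "allowed_elements", frozenset(self.allowed_elements))

    def allows(self, symbol: str) -> bool:
        return symbol in self.allowed_elements


@dataclass(frozen=True)
class RPosition:
    """One R-group position: a wildcard atom and the core atom it hangs from.

    ``label`` is the integer R label when the SMILES spells it (``[1*]``),
    otherwise a positional label assigned in atom-index order.
    """

    wildcard_index: int
    anchor_index: int
    bond_order: float
    label: int


@dataclass(frozen=True)
class GenericMolecule:
    """A query structure with at least one R position, plus its identifiers.

    ``num_heavy_atoms`` counts atoms that are neither hydrogen nor wildcard;
    ``exact_mol_wt`` is the monoisotopic mass with massless wildcards.
    """

    smiles: str
    source_ids: tuple
    num_heavy_atoms: int
    exact_mol_wt: float
    r_positions: tuple
    mol: Chem.Mol = field(repr=False, compare=False, default=None)

    @classmethod
    def from_smiles(cls, smiles: str, source_ids: Iterable[str]) -> "GenericMolecule":
        mol = parse_molecule(smiles)
        ids = tuple(dict.fromkeys(source_ids))
        return cls(
            smiles=canonical_smiles(mol),
            source_ids=ids,
            num_heavy_atoms=count_heavy_atoms(mol),
            exact_mol_wt=exact_molecular_weight(mol),
            r_positions=tuple(find_r_positions(mol)),
            mol=mol,
        )

    @property
    def is_query(self) -> bool:
        """True when the molecule is admissible as an expansion query."""
        return len(self.r_positions) >= 1


def parse_molecule(text: str) -> Chem.Mol:
    """Parse a SMILES or InChI string into a sanitized RDKit molecule.

    InChI input is detected by its ``InChI=`` prefix and validated by
    round-trip regeneration of a syntactically valid InChI. Unparsable or
    valence-invalid input raises :class:`MoleculeParseError` naming the text.
    """
    if not isinstance(text, str) or not text.strip():
        raise MoleculeParseError(text, "empty input")
    text = text.strip()
    if text.startswith("InChI="):
        mol = Chem.MolFromInchi(text, sanitize=True)
        if mol is None:
            raise MoleculeParseError(text, "invalid InChI")
        if not (Chem.MolToInchi(mol) or "").startswith("InChI="):
            raise MoleculeParseError(text, "InChI round-trip failed")
        return mol
    mol = Chem.MolFromSmiles(text, sanitize=True)
    if mol is None or mol.GetNumAtoms() == 0:
        raise MoleculeParseError(text, "invalid SMILES")
    return mol


def canonical_smiles(mol: Chem.Mol) -> str:
    """Canonical isomeric SMILES for ``mol`` (wildcards preserved)."""
    return Chem.MolToSmiles(mol)


def to_inchi(mol: Chem.Mol) -> Optional[str]:
    """Standard InChI for ``mol``; None when InChI generation fails."""
    inchi = Chem.MolToInchi(mol)
    return inchi if inchi else None


def is_wildcard(atom: Chem.Atom) -> bool:
    return atom.GetAtomicNum() == 0


def count_heavy_atoms(mol: Chem.Mol) -> int:
    """Number of atoms that are neither hydrogen nor wildcard."""
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (0, 1))


def exact_molecular_weight(mol: Chem.Mol) -> float:
    """Monoisotopic mass in daltons; wildcard atoms contribute zero mass."""
    if mol.GetNumAtoms() == 0:
        return 0.0
    return ExactMolWt(mol)


def passes_element_policy(mol: Chem.Mol, policy: ElementPolicy) -> bool:
    """True iff every non-wildcard atom's element is in the allowed set."""
    return all(
        policy.allows(a.GetSymbol()) for a in mol.GetAtoms() if not is_wildcard(a)
    )


def element_set(mol: Chem.Mol) -> frozenset:
    """Element symbols present in the molecule, wildcards excluded.

    Implicit hydrogens count: any atom with implicit or explicit Hs adds "H".
    """
    symbols = set()
    for a in mol.GetAtoms():
        if is_wildcard(a):
            continue
        symbols.add(a.GetSymbol())
        if a.GetTotalNumHs() > 0:
            symbols.add("H")
    return frozenset(symbols)


def find_r_positions(mol: Chem.Mol) -> list:
    """One :class:`RPosition` per wildcard atom, ascending by atom index.

    Labeled wildcards (``[1*]``, stored as an isotope) keep their label;
    unlabeled ones get the lowest free positive integers in index order.
    A degree-0 wildcard (isolated ``*``) is a structural error: it anchors
    to nothing and denotes no substitution site.
    """
    wildcards = [a for a in mol.GetAtoms() if is_wildcard(a)]
    used_labels = {a.GetIsotope() for a in wildcards if a.GetIsotope() > 0}
    positions = []
    next_label = 1
    for atom in wildcards:
        if atom.GetDegree() == 0:
            raise StructureError(
                f"isolated wildcard atom at index {atom.GetIdx()} in "
                f"{Chem.MolToSmiles(mol)!r}"
            )
        neighbor = atom.GetNeighbors()[0]
        bond = mol.GetBondBetweenAtoms(atom.GetIdx(), neighbor.GetIdx())
        if atom.GetIsotope() > 0:
            label = atom.GetIsotope()
        else:
            while next_label in used_labels:
                next_label += 1
            label = next_label
            used_labels.add(label)
        positions.append(
            RPosition(
                wildcard_index=atom.GetIdx(),
                anchor_index=neighbor.GetIdx(),
                bond_order=bond.GetBondTypeAsDouble(),
                label=label,
            )
        )
    return positions
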