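"""Deterministic synthetic fixtures with planted match classifications.

Every scaffold is a curated core built from the biological element set,
written as a construction template with labeled R sites (``[1*]``…) plus
one off-site attachment point (``[8*]``). From each scaffold the generator
plants, with known ground truth:

* *extended* candidates — one pool substituent grafted at every R site
  (all additions exclusively at R positions);
* *superstructure-only* candidates — R substituents plus one off-site
  methyl (an addition not at an R position);
* *decoys* — heavier structures sharing no embedding of any core;
* *light decoys* — truncations of the core lighter than every query, which
  the weight prefilter must exclude before any matching;
* *multi-entity* candidates — an extended structure dot-joined with a water
  component, exercising the disaggregation step.

Scaffold cores within one site-count family carry mutually exclusive
structural markers (aromatic ring / saturated N ring / sulfur chain /
chlorine / saturated carbocycle), and the substituent pool avoids those
markers, so cross-scaffold pairs are no-matches by construction.
Generation is a pure function of the spec: same seed, same bytes.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from rdkit import Chem

from .errors import FixtureError
from .molecules import (
    ElementPolicy,
    canonical_smiles,
    exact_molecular_weight,
    parse_molecule,
    passes_element_policy,
)

# ground-truth labels
EXTENDED = "RGROUP_EXTENDED"
SUPERSTRUCTURE = "CORE_SUPERSTRUCTURE"
NO_MATCH = "NO_MATCH"
LIGHT_DECOY = "LIGHT_DECOY"  # no-match AND excluded by the weight prefilter
MULTICOMPONENT_EXTENDED = "MULTICOMPONENT_EXTENDED"

#: default substituent pool: single atoms and multi-atom groups
DEFAULT_SUBSTITUENT_POOL = ("*C", "*CC", "*O", "*N", "*C(C)=O", "*OP(=O)(O)O")

# (construction template, light-decoy SMILES) per R-site count
_SCAFFOLDS: Dict[int, Tuple[Tuple[str, str], ...]] = {
    1: (
        ("[1*]c1ccc(O)c([8*])c1", "c1ccccc1"),
        ("[1*]C1CCN([8*])CC1", "C1CCNC1"),
        ("[1*]CC(=O)NCCS[8*]", "CC(=O)NC"),
    ),
    2: (
        ("[1*]NC(=O)C(Cl)([2*])C[8*]", "CC(C)Cl"),
        ("[1*]c1ccc([2*])c([8*])c1Cl", "c1ccccc1"),
    ),
    3: (
        ("[1*]C1C([2*])CC([3*])C1C[8*]", "C1CCC1"),
        ("[1*]c1cc([2*])cc([3*])c1[8*]", "CC=O"),
    ),
}

# heavy acyclic C/O decoys: no ring, no aromatic system, no N/S/Cl, so no
# scaffold core can embed in them
_DECOY_POOL = (
    "CCOC(C)CC(C)OC(C)C",
    "CCCOC(C)CC(C)OCC",
    "CCCCOC(C)CC(C)OC",
    "CC(C)(C)COC(C)CC(C)O",
    "CCOCC(C)(C)COC(C)C",
    "CCC(C)OC(C)CC(C)OC",
    "CC(O)C(C)(C)CC(C)OCC",
    "CCCC(C)OCC(C)(C)CO",
    "CCOC(C)C(C)CC(C)OC",
    "CC(C)CC(C)(O)CC(C)OC",
    "CCCOCC(C)(C)C(C)OC",
    "CC(C)OC(C)CC(C)(C)CO",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture; counts are per scaffold."""

    seed: int = 0
    n_scaffolds: int = 3
    r_sites_per_scaffold: int = 1
    substituent_pool: tuple = DEFAULT_SUBSTITUENT_POOL
    n_extended: int = 2
    n_superstructure_only: int = 2
    n_decoys: int = 2
    n_light_decoys: int = 1
    n_multicomponent: int = 1

    def __post_init__(self):
        if self.r_sites_per_scaffold not in _SCAFFOLDS:
            raise FixtureError(
                f"r_sites_per_scaffold must be in {sorted(_SCAFFOLDS)}"
            )
        for name in (
            "n_scaffolds",
            "n_extended",
            "n_superstructure_only",
            "n_decoys",
            "n_light_decoys",
            "n_multicomponent",
        ):
            if getattr(self, name) < 0:
                raise FixtureError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """Expected classification per (query SMILES, candidate cid).

    ``substituents`` records, for planted extended candidates, the pool
    group grafted at each R label.
    """

    labels: Dict[Tuple[str, int], str] = field(default_factory=dict)
    substituents: Dict[Tuple[str, int], Dict[int, str]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "labels": [
                {"query": q, "cid": c, "label": lbl}
                for (q, c), lbl in sorted(self.labels.items())
            ],
            "substituents": [
                {"query": q, "cid": c, "groups": {str(k): v for k, v in groups.items()}}
                for (q, c), groups in sorted(self.substituents.items())
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class FixtureSet:
    spec: FixtureSpec
    queries: List[Tuple[str, str]]
    library: List[Tuple[int, str]]
    ground_truth: GroundTruth

    def write_query_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            for ident, smiles in self.queries:
                handle.write(f"{ident}\t{smiles}\n")

    def write_library_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            for cid, smiles in self.library:
                handle.write(f"{cid}\t{smiles}\n")

    def write_ground_truth(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(self.ground_truth.to_json())


def _zip_template(template: str, fills: Dict[int, str]) -> Chem.Mol:
    """Graft labeled fragments onto a construction template.

    ``fills`` maps dummy labels to fragment SMILES whose attachment point is
    written ``*``; every label present in the template must be filled (the
    off-site label 8 with ``[H]`` when no off-site group is wanted).
    """
    pieces = [Chem.MolFromSmiles(template)]
    if pieces[0] is None:
        raise FixtureError(f"bad template {template!r}")
    for label, frag_smiles in fills.items():
        labeled = frag_smiles.replace("*", f"[{label}*]", 1)
        frag = Chem.MolFromSmiles(labeled)
        if frag is None:
            raise FixtureError(f"bad fragment {frag_smiles!r}")
        pieces.append(frag)
    combined = pieces[0]
    for frag in pieces[1:]:
        combined = Chem.CombineMols(combined, frag)
    params = Chem.MolzipParams()
    params.label = Chem.MolzipLabel.Isotope
    zipped = Chem.molzip(combined, params)
    zipped = Chem.RemoveHs(zipped)
    Chem.SanitizeMol(zipped)
    return zipped


def _query_smiles(template: str) -> str:
    return canonical_smiles(_zip_template(template, {8: "*[H]"}))


def _candidate_smiles(template: str, site_subs: Dict[int, str], offsite: str) -> str:
    fills = {8: offsite}
    fills.update(site_subs)
    return canonical_smiles(_zip_template(template, fills))


def _sample_combos(rng: random.Random, pool, n_sites, n_wanted, taken):
    """Distinct substituent tuples yielding structurally distinct candidates."""
    combos = []
    attempts = 0
    while len(combos) < n_wanted:
        attempts += 1
        if attempts > 200:
            raise FixtureError(
                "substituent pool too small for the requested candidate counts"
            )
        combo = tuple(rng.sample(pool, n_sites))
        if combo not in taken:
            taken.add(combo)
            combos.append(combo)
    return combos


def generate_fixture(spec: FixtureSpec = FixtureSpec()) -> FixtureSet:
    """Build queries, a candidate library and ground truth from ``spec``."""
    rng = random.Random(spec.seed)
    templates = _SCAFFOLDS[spec.r_sites_per_scaffold]
    if spec.n_scaffolds > len(templates):
        raise FixtureError(
            f"at most {len(templates)} scaffolds available with "
            f"{spec.r_sites_per_scaffold} R sites"
        )
    n_sites = spec.r_sites_per_scaffold
    if n_sites == 1 and spec.n_extended + spec.n_multicomponent > len(
        spec.substituent_pool
    ):
        raise FixtureError(
            "substituent pool too small: extended and multi-entity candidates "
            "need distinct substituents"
        )
    n_decoys_total = spec.n_scaffolds * spec.n_decoys
    if n_decoys_total > len(_DECOY_POOL):
        raise FixtureError(
            f"decoy pool exhausted: need {n_decoys_total}, have {len(_DECOY_POOL)}"
        )

    chosen = templates[: spec.n_scaffolds]
    queries: List[Tuple[str, str]] = []
    library: List[Tuple[int, str]] = []
    truth = GroundTruth()
    decoys = rng.sample(_DECOY_POOL, n_decoys_total) if n_decoys_total else []
    policy = ElementPolicy()

    query_smiles = [_query_smiles(tpl) for tpl, _ in chosen]
    next_cid = 1001

    def add_candidate(smiles: str, labels: Dict[str, str]) -> int:
        nonlocal next_cid
        cid = next_cid
        next_cid += 1
        library.append((cid, smiles))
        for qsmi, lbl in labels.items():
            truth.labels[(qsmi, cid)] = lbl
        return cid

    for s_idx, (template, light) in enumerate(chosen):
        qsmi = query_smiles[s_idx]
        queries.append((f"CHEBI:9{s_idx:04d}", qsmi))
        other_queries = [q for q in query_smiles if q != qsmi]
        taken: set = set()

        ext_combos = _sample_combos(
            rng, spec.substituent_pool, n_sites, spec.n_extended, taken
        )
        multi_combos = _sample_combos(
            rng, spec.substituent_pool, n_sites, spec.n_multicomponent, taken
        )
        sup_combos = _sample_combos(
            rng, spec.substituent_pool, n_sites, spec.n_superstructure_only, set()
        )

        for combo in ext_combos:
            site_subs = {i + 1: s for i, s in enumerate(combo)}
            csmi = _candidate_smiles(template, site_subs, "*[H]")
            labels = {qsmi: EXTENDED}
            labels.update({oq: NO_MATCH for oq in other_queries})
            cid = add_candidate(csmi, labels)
            truth.substituents[(qsmi, cid)] = dict(site_subs)

        for combo in sup_combos:
            site_subs = {i + 1: s for i, s in enumerate(combo)}
            csmi = _candidate_smiles(template, site_subs, "*C")
            labels = {qsmi: SUPERSTRUCTURE}
            labels.update({oq: NO_MATCH for oq in other_queries})
            add_candidate(csmi, labels)

        for combo in multi_combos:
            site_subs = {i + 1: s for i, s in enumerate(combo)}
            csmi = _candidate_smiles(template, site_subs, "*[H]") + ".O"
            labels = {qsmi: MULTICOMPONENT_EXTENDED}
            labels.update({oq: NO_MATCH for oq in other_queries})
            add_candidate(csmi, labels)

        for _ in range(spec.n_decoys):
            csmi = canonical_smiles(parse_molecule(decoys.pop()))
            add_candidate(csmi, {q: NO_MATCH for q in query_smiles})

        for _ in range(spec.n_light_decoys):
            csmi = canonical_smiles(parse_molecule(light))
            labels = {qsmi: LIGHT_DECOY}
            labels.update({oq: NO_MATCH for oq in other_queries})
            add_candidate(csmi, labels)

    # construction sanity: every structure parses, obeys the element policy,
    # and light decoys sit below every query weight
    min_query_wt = min(
        exact_molecular_weight(parse_molecule(q)) for _, q in queries
    )
    for cid, smiles in library:
        mol = parse_molecule(smiles)
        if not passes_element_policy(mol, policy):
            raise FixtureError(f"candidate {cid} violates the element policy")
    for (qsmi, cid), lbl in truth.labels.items():
        if lbl == LIGHT_DECOY:
            smiles = dict(library)[cid]
            if exact_molecular_weight(parse_molecule(smiles)) >= min_query_wt:
                raise FixtureError(f"light decoy {cid} is not light")

    return FixtureSet(
        spec=spec, queries=queries, library=library, ground_truth=truth
    )


def fig2a_fixture(seed: int = 0) -> FixtureSet:
    """Single-query library with the 4-superstructure / 2-extended pattern.

    Two candidates substituted only at the R position, two carrying an
    additional off-site group, and two decoys: expansion must report a
    superstructure list of four and an extended list of two.
    """
    return generate_fixture(
        FixtureSpec(
            seed=seed,
            n_scaffolds=1,
            r_sites_per_scaffold=1,
            n_extended=2,
            n_superstructure_only=2,
            n_decoys=2,
            n_light_decoys=0,
            n_multicomponent=0,
        )
    )
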