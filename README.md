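# biorgroup

Expansion of generic ("Markush") molecules into fully defined molecular
instances, by matching their cores against a candidate compound library.

Curated biochemical resources describe many reaction participants as
*generic* structures: SMILES containing wildcard atoms (`*`, or labeled
`[1*]`) that stand for unspecified substituents — R-groups. Such entries
represent whole chemical families, which makes them unusable as concrete
inputs for cheminformatics tools and machine-learning models. `biorgroup`
resolves them: given a query file of identifier↔SMILES pairs and a
compound library (identifier + SMILES/InChI records, a PubChem-style
snapshot at any scale), it finds every library compound that contains a
query's defined core and classifies each match:

* **core superstructure** — the candidate contains the core; additional
  atoms may sit anywhere;
* **R-group extended** — every addition sits *exclusively* at the R
  positions, one connected substituent group per position (the hydrogen-only
  group is admissible and configurable).

Matching is stereochemistry-aware: chiral-center parities and double-bond
configurations defined on the query must be preserved (query-undefined
stereo matches anything); formal charge and isotope must match exactly on
core atoms; tautomers are not enumerated. Classification is existential
over embeddings — a candidate is extended if *any* valid embedding of the
core leaves no leftover atoms.

The library-scale procedure has three steps per query, after a strict
monoisotopic-weight prefilter (only candidates heavier than the query are
considered):

1. match every candidate under a per-pair timeout (default 10 s);
2. disaggregate multi-entity candidates (salts, mixtures) and re-match
   each component heavier than the query, keeping the composite entry's
   identifiers as provenance;
3. classify every core match and emit two deduplicated, deterministically
   ordered lists (superstructure and extended) per query.

Results are written as an eight-column CSV (optionally gzipped):
`smiles, chebi, num_heavy_atoms, exact_mol_wt, core_superstructure_smiles,
core_superstructure_pubchem_cid, rgroup_extended_smiles,
rgroup_extended_pubchem_cid`, with JSON-encoded list cells (the cid
columns are lists of lists: one matched structure can carry several
library identifiers).

The package also ships the query-selection filters with full accounting
(≥1 R-group, ≥6 heavy atoms, a biological-element whitelist of
H C N O Na Mg P S Cl K Ca), an exhaustive-embedding oracle used to certify
the matcher on desk-scale instances, stereocenter and NP-likeness
analytics, and a deterministic fixture generator with planted ground
truth.

## Worked example

```bash
python examples/expand_generic_molecule.py
```

```
query *c1ccc(O)cc1  (7 heavy atoms, 93.0340 Da)
library: 6 compounds, 5 matching attempts
core superstructures (contain the core, additions anywhere):
          Cc1ccc(O)cc1  cids=[1]
         CCc1ccc(O)cc1  cids=[2]
       Cc1cc(C)cc(O)c1  cids=[3]
       Cc1ccc(O)c(C)c1  cids=[4]
r-group extended (additions exclusively at the R position):
          Cc1ccc(O)cc1  cids=[1]
         CCc1ccc(O)cc1  cids=[2]
```

The query is the 4-substituted-phenol family. Four of the six library
compounds contain the phenol core and appear as superstructures; only the
two whose single addition hangs at the marked position are R-group
extended. Compound 5 is heavier but lacks the core (no match), and
compound 6 is lighter than the query, so the weight prefilter skips it
without a matching attempt (5 attempts for 6 compounds). Other examples:
`build_dataset.py` (full pipeline to the eight-column CSV),
`np_likeness.py` (fragment-ratio natural-product-likeness scoring) and
`timeout_sweep.py` (coverage versus per-pair budget).

A thin CLI wraps the same library calls:

```bash
biorgroup build queries.tsv library.tsv out.csv.gz   # full pipeline
biorgroup filter queries.tsv                         # selection report only
biorgroup expand '*c1ccc(O)cc1' library.tsv          # one query
biorgroup validate library.tsv --queries queries.tsv # analytics
```

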