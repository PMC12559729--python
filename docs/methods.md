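# Methods

## The matching model

A *generic molecule* is a connected molecular graph with at least one
wildcard atom (atomic number 0). The non-wildcard part is the **core**;
each wildcard marks an **R position**, anchored at the core atom it is
bonded to. A fully defined *candidate* matches the core when there is an
injective, adjacency-preserving embedding of all query atoms into the
hydrogen-explicit candidate such that:

* element, formal charge and isotope agree exactly on every core atom
  pair (wildcards match any atom, including hydrogen);
* every query bond maps to a candidate bond of the same order, after one
  shared aromaticity perception (RDKit default sanitization), so SMILES
  dialect differences cannot create false negatives;
* every chiral-center parity and double-bond configuration *defined on
  the query* is defined on the candidate and preserved; query-undefined
  stereo matches anything. Enhanced stereo (stereo groups) is ignored.

Given an embedding, the candidate partitions into the core image,
**substituent groups** and **leftovers**. Hydrogens on core-image atoms
belong to the core (an extra hydrogen is never an addition). A connected
component of the remaining atoms is the substituent group of an R
position iff it contains exactly that position's wildcard image and
touches the core only through that position's anchor image; everything
else — including components bridging two R positions or bonded to a
non-anchor core atom — is leftover. A candidate bond between two
core-image atoms that is not the image of a query bond (the core embedded
in a ring it does not declare) also counts as an off-site addition.

Classification is **existential over embeddings**:

* `RGROUP_EXTENDED` — some embedding has no leftovers, no extra
  core-core bonds, and one substituent group per R position. The
  hydrogen-only group (wildcard image is a hydrogen) is admissible by
  default (`allow_hydrogen_substituent`); with
  `require_all_r_substituted` set and hydrogen disallowed, every R
  position needs a heavy-atom group.
* `CORE_SUPERSTRUCTURE` — the core embeds, but every embedding leaves
  additions off the R positions.
* no-match otherwise. Tautomers are never enumerated: a candidate
  matching only a tautomeric form of the core (e.g. enol vs keto) is a
  no-match.

The extended set is by construction a subset of the superstructure set.

A consequence of existential classification worth knowing: for a query
like `*[C@@H](N)C(=O)O`, the candidate with the *inverted* center,
`C[C@H](N)C(=O)O`, still core-matches — the wildcard takes the
stereocenter's hydrogen, the methyl becomes an off-site leftover, and the
parity is preserved in that embedding. It is a superstructure, not an
extension. Stereo sensitivity in the strict sense (flip → no-match) holds
when the defined center is remote from the R anchor.

## Implementation and the oracle

The production matcher builds an RDKit substructure query from the
generic molecule (wildcards become match-any query atoms; their isotope
labels are bookkeeping and are cleared for matching), enumerates
embeddings into the hydrogen-explicit candidate with chirality-aware
matching, then applies the exactness post-checks RDKit's default atom
comparison omits (formal charge, isotope, defined-ness of matched stereo
descriptors) and the partition analysis above.

An independent **oracle** (`oracle_classify`) re-derives the same
contract by exhaustive subgraph-monomorphism enumeration (VF2 via
networkx) with hand-rolled parity arithmetic: tetrahedral centers are
compared through the permutation parity between the two stored
neighbour orders (the single implicit-hydrogen slot paired with the
candidate's single unmatched neighbour), double bonds through
reference-atom side flips. The oracle refuses candidates above 20 heavy
atoms; it certifies desk-scale behaviour, and the test suite requires
100% agreement with the matcher over 500+ generated pairs.

## Library-scale expansion

`expand_query` applies a strict monoisotopic-weight prefilter (only
candidates heavier than the query are matched; the same mass convention
on both sides, wildcards massless), then the three-step procedure: match
under a per-pair timeout; for matched multi-entity candidates, split
components and re-match each component heavier than the query, keeping
the composite identifiers as provenance; classify every match. Matched
structures are deduplicated on standard InChI with identifier lists
merged sorted-unique, and both output lists are ordered by
(monoisotopic mass, canonical SMILES), so runs are reproducible
byte-for-byte.

Timeouts are wall-clock per (query, candidate) pair by default. A single
substructure call cannot be interrupted mid-call, so the budget is
checked at call and embedding boundaries — adequate at the problem sizes
this package targets. For reproducible timeout experiments every entry
point also accepts a simulated per-pair *cost model*; a pair then times
out iff its simulated cost exceeds the budget, with no real waiting. The
timeout-sensitivity analysis samples queries at evenly spaced indices of
the weight-sorted sequence (ties broken by canonical SMILES) and reports
coverage — evaluated pairs over total pairs — per budget; coverage is
non-decreasing in the budget by construction.

## Selection filters and accounting

Query selection retains molecules with ≥1 R position, ≥6 heavy atoms
(wildcards and hydrogens do not count as heavy — the two worked
exclusions `*CCC=O` and `*SO` fall below six under either wildcard
convention, and excluding wildcards is the common toolkit convention),
and only whitelisted elements (H, C, N, O, Na, Mg, P, S, Cl, K, Ca).
Exclusions are accounted in that order, each molecule counted once under
its first failure, so reports decompose exactly:
`unique = retained + no_rgroup + excluded_heavy + excluded_elements`.
Identifier merging uses verbatim SMILES string equality by default
(canonical-form merging is available as an option and reported
separately). The pipeline emits either every unique molecule
(`full` mode, non-queries carrying four empty lists) or retained queries
only (`expanded-only`).

## Dataset serialization

The writer produces RFC-4180 CSV with the fixed eight-column header,
JSON-array list cells, cid cells as lists of lists, `[]` for empty lists,
and masses at five decimal places; gzip output zeroes the archive mtime
so identical records give identical bytes. The reader enforces the
schema (naming missing/extra columns), reports per-row typed errors with
the row index, and also tolerates single-quoted Python-literal list
cells. Round-trip equality is exact except for the mass column, compared
at 1e-4 Da to match the 5-decimal writer.

## NP-likeness scorer

The scorer is a fragment-frequency log-ratio model: atom-centered
circular fragments of radius 0–2 (Morgan environments) are counted in a
"natural" and a "synthetic" training collection; a fragment's
contribution is `log10(f_nat + s) − log10(f_syn + s)` on relative
frequencies with pseudo-count `s` (default 1e-6), computed as a
difference of logarithms so that swapping the collections negates every
contribution exactly. A molecule's score is the multiplicity-weighted sum
of its fragments' contributions divided by its heavy-atom count; unseen
fragments contribute zero. This is a self-trained approximation of the
classical fragment-based natural-product-likeness score, not a
re-distribution of any published trained model. "Chiral centers" in the
stereo statistics are tetrahedral stereocenters; stereogenic double bonds
are counted separately.

## Fixtures: what they emulate and what they do not

The fixture generator plants, per curated scaffold, extended candidates
(pool substituents grafted at every R site), superstructure-only
candidates (plus one off-site methyl), heavy no-match decoys, light
decoys that the weight prefilter must skip, and multi-entity candidates
(extended structure dot-joined with water). Scaffold cores within a
family carry mutually exclusive structural markers (aromatic ring,
saturated N-ring, sulfur chain, chlorine, saturated carbocycle) and the
substituent pool (methyl, ethyl, hydroxyl, amino, acetyl, phosphate)
avoids them, so cross-scaffold pairs are no-matches by construction;
generation validates every structure and the light-decoy weight bound,
and is a pure function of the seed.

Two deliberate departures from strict literality: a molecule genuinely
*containing* the core can never weigh less than the query (the query is
the core minus one anchor hydrogen), so light decoys are truncations of
the core rather than superstructures; and the planted
4-superstructure / 2-extended library pattern uses synthetic structures,
not any published example's exact molecules.

Passing on these fixtures certifies the matching semantics, the
accounting identities and the serialization contract. It does not
certify behaviour on real library data at scale: natural-product
decoration chemistry, pathological symmetry (which inflates embedding
counts), valence-exotic species and million-compound throughput are out
of fixture scope. Default problem sizes (3–7 queries, 16–24 candidates
per fixture, 500+ oracle-checked pairs) keep the whole suite and the
acceptance script within seconds on one CPU while exercising every code
path; they are the package's chosen desk scale, and library-scale runs
simply take longer.

## Known limitations

* Real wall-clock timeouts cannot pre-empt a pathological single
  substructure call; the cost-model path exists for exact experiments.
* Embedding enumeration is capped at 100,000 matches per pair; molecules
  with astronomically many automorphisms could in principle exhaust the
  cap before an extended embedding is found.
* The compound store is an in-memory InChI-keyed index behind a narrow
  interface; swapping in an embedded relational database is a local
  change but not provided.
* InChI validation follows RDKit's InChI build; exotic species that
  RDKit's InChI layer rejects are counted as parse rejections.
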