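"""Expand one generic molecule against a small in-memory library.

The query ``*c1ccc(O)cc1`` is a para-substituted phenol family: the ``*``
marks the R position. Candidates containing the phenol core are reported
as core superstructures; the subset whose only addition hangs at the R
position is reported as R-group extended.
"""

from biorgroup import GenericMolecule, expand_query, ingest_library

LIBRARY = [
    (1, "Cc1ccc(O)cc1"),        # methyl exactly at R -> extended
    (2, "CCc1ccc(O)cc1"),       # ethyl at R -> extended
    (3, "Cc1cc(C)cc(O)c1"),     # two additions -> superstructure only
    (4, "Cc1ccc(O)c(C)c1"),     # R substituent plus off-site methyl
    (5, "CCCCCCCC"),            # heavier, but no phenol core
    (6, "CCO"),                 # lighter than the query: never matched
]

query = GenericMolecule.from_smiles("*c1ccc(O)cc1", ["CHEBI:example"])
store, report = ingest_library(LIBRARY)
result = expand_query(query, store)

print(f"query {query.smiles}  ({query.num_heavy_atoms} heavy atoms, "
      f"{query.exact_mol_wt:.4f} Da)")
print(f"library: {len(store)} compounds, {result.n_match_calls} matching attempts")
print("core superstructures (contain the core, additions anywhere):")
for entry in result.superstructure:
    print(f"  {entry.smiles:>20s}  cids={list(entry.cids)}")
print("r-group extended (additions exclusively at the R position):")
for entry in result.rgroup_extended:
    print(f"  {entry.smiles:>20s}  cids={list(entry.cids)}")
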