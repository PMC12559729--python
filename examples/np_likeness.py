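"""Train the fragment-ratio NP-likeness scorer and score some molecules.

The scorer learns log10 frequency ratios of circular fragments (radius
0-2) between a "natural" and a "synthetic" training collection. Positive
scores mean the molecule's fragments are more typical of the natural set;
the score is normalised by heavy-atom count, and swapping the training
collections negates it exactly.
"""

from biorgroup import np_score, parse_molecule, train_np_scorer

natural = [parse_molecule(s) for s in [
    "C[C@H](O)CC(O)=O",
    "OC[C@H]1O[C@@H](O)[C@H](O)[C@@H]1O",
    "C[C@@H]1CC[C@H](C(C)C)C(=O)C1",
    "O=C(O)C[C@H](O)C[C@H](O)CC(=O)O",
]]
synthetic = [parse_molecule(s) for s in [
    "c1ccccc1C(=O)OC",
    "CC(C)(C)OC(=O)NC",
    "Clc1ccc(Cl)cc1",
    "COc1ccc(S(N)(=O)=O)cc1",
]]

table = train_np_scorer(natural, synthetic)
print(f"trained on {table.n_natural} natural / {table.n_synthetic} synthetic "
      f"molecules; {len(table.scores)} fragments")

probes = {
    "sugar (natural-like)": "OC[C@H]1O[C@@H](O)[C@H](O)[C@@H]1O",
    "hydroxy acid": "CC(O)CC(O)=O",
    "aryl ester (synthetic-like)": "c1ccccc1C(=O)OCC",
    "chlorobenzene": "Clc1ccccc1Cl",
}
for name, smiles in probes.items():
    score = np_score(parse_molecule(smiles), table)
    print(f"  {name:<28s} {smiles:<32s} score={score:+.2f}")
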