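"""Featurize one drug-target pair into the 730-value descriptor vector.

A protein is encoded from its sequence (20 AAC + 240 Moran + 147 CTD =
407 values) and a ligand from its SMILES (30 constitutional + 23
connectivity + 6 property + 7 kappa + 12 charge + 166 MACCS + 79 E-state
= 323 values); a pair row is their concatenation.
"""

from dtiscreen.drug_descriptors import drug_features
from dtiscreen.protein_descriptors import protein_features
from dtiscreen.synthetic_fixtures import random_protein

seq = random_protein(80, seed=1, id="demo_protein")
protein = protein_features(seq)
drug = drug_features("CC(=O)OC1=CC=CC=C1C(=O)O", "aspirin")

print(f"protein block: {len(protein.values)} values")
print(f"  aac.A   (alanine fraction)        = {protein.values[0]:.4f}")
print(f"  {protein.labels[20]:<32} = {protein.values[20]:.4f}")
print(f"  {protein.labels[260]:<32} = {protein.values[260]:.4f}")
print(f"drug block:    {len(drug.values)} values")
labels = list(drug.labels)
for name in ("const.n_heavy", "const.n_hbd", "prop.logp", "prop.tpsa"):
    i = labels.index(name)
    print(f"  {name:<32} = {drug.values[i]:.4f}")
print(f"pair width:    {len(protein.values) + len(drug.values)}")
print()
print("Each pair row is protein || drug; identical entities always map to")
print("identical blocks, so matrices over many pairs are cached per entity.")
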