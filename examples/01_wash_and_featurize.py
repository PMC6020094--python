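"""Wash a small molecule set (salt stripping, largest fragment) and compute
fingerprints and descriptors."""

import admetkit as ak
from admetkit.chem_io import record_from_smiles

# salts and mixtures: washing disconnects simple metal salts, keeps the
# largest fragment and normalizes hydrogens
for smi in ["CCO.Cl", "CC(=O)[O-].[Na+]", "c1ccccc1C(=O)O"]:
    rec = record_from_smiles(smi)
    print(f"{smi:25s} -> {rec.smiles}")

corpus = ak.generate_molecule_corpus(10, seed=0)
maccs = ak.compute_fingerprints(corpus, "maccs")
desc = ak.compute_descriptors(corpus, {"property", "constitution"})
print(f"\nMACCS matrix: {maccs.n} molecules x {maccs.p} bits")
print(f"descriptors:  {desc.n} molecules x {desc.p} columns "
      f"(property family is 6 of them)")
# The fingerprint width is fixed per kind (MACCS = 167 keys); descriptor
# columns are tagged by family so downstream steps can slice them.
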