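"""Screen molecules against the five drug-likeness rules and render a
systematic ADMET profile with +/- symbols."""

import numpy as np

import admetkit as ak
from admetkit.chem_io import record_from_smiles
from admetkit.druglikeness import results_table
from admetkit.modeling import ModelConfig, train
from admetkit.search_profile import profile_table, systematic_profile

aspirin = record_from_smiles("CC(=O)Oc1ccccc1C(=O)O", id="aspirin")
greasy = record_from_smiles("C" * 30, id="C30-alkane")
table = results_table(ak.evaluate_all([aspirin, greasy]))
print(table.to_string(index=False))

# a toy endpoint registry: one classifier trained on synthetic labels
corpus = ak.generate_molecule_corpus(30, seed=5)
fm = ak.compute_fingerprints(corpus, "ecfp4")
y = (np.arange(30) % 2).astype(float)
clf = train(ak.LabeledDataset(fm, y, task="classification"),
            ModelConfig("rf", "classification", {"estimators": 50}, seed=5))
rows = systematic_profile(aspirin, {"bbb": clf, "herg": clf})
print()
print(profile_table(rows)[["endpoint", "probability", "symbol"]].to_string(index=False))
# Symbols encode the probability band: e.g. 0.9 < p -> "+++", p <= 0.1 -> "---".
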