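"""Accurate, range and similarity search over a local ADMET record store."""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

import admetkit as ak
from admetkit.search_profile import AdmetRecordStore, accurate_search, range_search, similarity_search

corpus = ak.generate_molecule_corpus(20, seed=6)
df = pd.DataFrame({
    "id": [r.id for r in corpus],
    "smiles": [r.smiles for r in corpus],
    "cas": [f"100-{i:02d}-5" for i in range(20)],
    "iupac_name": [f"synthetic compound {i}" for i in range(20)],
    "class": "basic", "subclass": "logS",
    "value": np.round(np.linspace(-4, 0, 20), 2),
    "reference": "synthetic store",
})
with tempfile.TemporaryDirectory() as td:
    path = Path(td) / "store.csv"
    df.to_csv(path, index=False)
    store = AdmetRecordStore.from_csv(path)  # canonicalizes SMILES, fills MW/AlogP/HBA/HBD

    print("accurate (by SMILES):",
          accurate_search(store, "smiles", corpus[0].smiles)["id"].tolist())
    hits = range_search(store, {"MW": (100, 200), "HBD": (0, 2)})
    print(f"range MW 100-200 & HBD 0-2: {len(hits)} entries")
    top = similarity_search(store, corpus[3], "ecfp4", "tanimoto", top_k=3)
    for h in top:
        print(f"  {h.entry_id}: tanimoto {h.score:.3f}")
# The top similarity hit for a stored molecule is itself, at score 1.0.
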