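import numpy as np
import pandas as pd
import pytest

import admetkit as ak
from admetkit.synthetic import SyntheticSpec


@pytest.fixture(scope="session")
def corpus():
    return ak.generate_molecule_corpus(50, seed=11)


@pytest.fixture(scope="session")
def salty_corpus():
    return ak.generate_molecule_corpus(50, seed=12, include_salts=True)


@pytest.fixture(scope="session")
def regression_dataset():
    spec = SyntheticSpec(n=120, n_features=15, n_informative=3, noise_sigma=0.5, seed=21)
    return ak.generate_qsar_dataset(spec)


@pytest.fixture(scope="session")
def classification_dataset():
    spec = SyntheticSpec(
        n=200, task="classification", n_features=10, n_informative=4,
        noise_sigma=0.5, class_balance=0.5, seed=22,
    )
    return ak.generate_qsar_dataset(spec)


@pytest.fixture()
def store_csv(tmp_path, corpus):
    entries = corpus[:20]
    df = pd.DataFrame(
        {
            "id": [r.id for r in entries],
            "smiles": [r.smiles for r in entries],
            "cas": [f"100-{i:02d}-5" for i in range(20)],
            "iupac_name": [f"Synthetic Compound {i}" for i in range(20)],
            "class": ["basic"] * 10 + ["T"] * 10,
            "subclass": "logS",
            "value": np.linspace(-3, 1, 20),
            "reference": "synthetic fixture",
        }
    )
    path = tmp_path / "store.csv"
    df.to_csv(path, index=False)
    return path
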