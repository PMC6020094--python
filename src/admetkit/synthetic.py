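"""Synthetic molecule corpora and QSAR datasets with known ground truth.

The corpus generator assembles valid SMILES from a bundled fragment grammar
(ring scaffolds, chains and common functional groups), optionally adding
counter-ion fragments so washing behavior can be exercised; distinctness is
enforced on canonical SMILES. The dataset generator draws standard-normal
features and builds a linear response y = X beta + eps; classification labels
threshold the logistic-transformed score at the empirical quantile matching
the requested class balance, so balance is exact up to ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import MoleculeRecord
from .dataprep import LabeledDataset
from .features import FeatureMatrix

_SCAFFOLDS = [
    "c1ccccc1", "c1ccncc1", "c1ccsc1", "c1ccoc1", "c1cnccn1",
    "C1CCCCC1", "C1CCNCC1", "C1CCOCC1", "C1CCCC1", "C1CCOC1",
    "c1ccc2ccccc2c1", "c1ccc2[nH]ccc2c1",
]
_LINKERS = ["", "C", "CC", "CCC", "C(C)", "CC(C)", "C=C", "CO", "CN", "C(=O)", "S", "O", "N"]
_GROUPS = [
    "O", "N", "C(=O)O", "C(=O)N", "C#N", "F", "Cl", "Br", "C(F)(F)F",
    "S(=O)(=O)N", "OC", "N(C)C", "C(C)=O", "[N+](=O)[O-]", "",
]
_COUNTER_IONS = ["Cl", "[Na+]", "[K+]", "O=C(O)C(=O)O", "OS(=O)(=O)O"]


@dataclass
class SyntheticSpec:
    """Conditions for a synthetic QSAR dataset."""

    n: int = 300
    task: str = "regression"
    n_features: int = 50
    n_informative: int = 5
    effect_sizes: np.ndarray | None = None
    noise_sigma: float = 0.5
    class_balance: float = 0.5
    seed: int = 0


def generate_molecule_corpus(
    n: int, seed: int = 0, include_salts: bool = False
) -> list[MoleculeRecord]:
    """Generate *n* distinct valid molecules; with *include_salts*, 20% carry
    a counter-ion fragment."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    stall = 0  # consecutive attempts without a new distinct molecule
    while len(records) < n:
        if stall > 5000:
            raise ValueError(
                "fragment grammar exhausted; maximum distinct corpus size "
                f"is about {len(records)}"
            )
        stall += 1
        scaffold = _SCAFFOLDS[rng.integers(len(_SCAFFOLDS))]
        smi = scaffold
        for _ in range(rng.integers(1, 4)):
            linker = _LINKERS[rng.integers(len(_LINKERS))]
            group = _GROUPS[rng.integers(len(_GROUPS))]
            if linker or group:
                smi = f"{smi}{linker}{group}" if rng.random() < 0.7 else f"{group}{linker}{smi}" if group else smi
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        stall = 0
        out_smi = canonical
        if include_salts and rng.random() < 0.2:
            ion = _COUNTER_IONS[rng.integers(len(_COUNTER_IONS))]
            out_smi = f"{canonical}.{ion}"
            mol = Chem.MolFromSmiles(out_smi)
        records.append(
            MoleculeRecord(
                id=f"syn{len(records)}",
                smiles=Chem.MolToSmiles(mol),
                structure=mol,
                source_index=len(records),
            )
        )
    return records


def generate_qsar_dataset(spec: SyntheticSpec) -> tuple[LabeledDataset, dict]:
    """Generate a labeled dataset plus its ground truth.

    Returns ``(dataset, truth)`` where ``truth`` holds the informative
    feature names and their coefficients.
    """
    if spec.n_informative > spec.n_features:
        raise ValueError("n_informative must be <= n_features")
    effects = spec.effect_sizes
    if effects is None:
        effects = np.linspace(1.0, 2.0, spec.n_informative) if spec.n_informative else np.array([])
    effects = np.asarray(effects, dtype=float)
    if spec.n_informative == 0 and effects.size:
        raise ValueError("n_informative is 0 but effect sizes were supplied")
    if effects.size != spec.n_informative:
        raise ValueError("effect_sizes length must equal n_informative")

    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.n, spec.n_features))
    beta = np.zeros(spec.n_features)
    informative_idx = np.arange(spec.n_informative)
    beta[informative_idx] = effects
    score = X @ beta
    cols = [f"x{j}" for j in range(spec.n_features)]
    ids = [f"s{i}" for i in range(spec.n)]
    df = pd.DataFrame(X, index=ids, columns=cols)
    fm = FeatureMatrix(df, "descriptor", pd.Series({c: "synthetic" for c in cols}))

    if spec.task == "regression":
        y = score + rng.normal(0, spec.noise_sigma, spec.n)
        ds = LabeledDataset(fm, y, endpoint="synthetic", task="regression")
    elif spec.task == "classification":
        noisy = score + rng.normal(0, spec.noise_sigma, spec.n)
        logit = 1 / (1 + np.exp(-noisy))
        # threshold at the empirical quantile so the balance is exact
        thresh = np.quantile(logit, 1 - spec.class_balance)
        y = (logit > thresh).astype(float)
        ds = LabeledDataset(fm, y, endpoint="synthetic", task="classification")
    else:
        raise ValueError(f"unknown task: {spec.task!r}")

    truth = {
        "informative_features": [cols[j] for j in informative_idx],
        "coefficients": dict(zip([cols[j] for j in informative_idx], effects)),
    }
    return ds, truth
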