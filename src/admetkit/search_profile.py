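"""Local ADMET record store with accurate / range / similarity search, and
the per-molecule systematic ADMET profile.

The store is a CSV with columns: entry id, smiles, cas, iupac_name, class
(basic/A/D/M/E/T), subclass, value, MW, AlogP, HBA, HBD, reference. SMILES
are canonicalized at load and missing MW/AlogP/HBA/HBD are computed then.

Similarity search supports the five fingerprints (fp2, maccs, ecfp2/4/6)
under Tanimoto |A&B|/|A|B| or Dice 2|A&B|/(|A|+|B|) on bit sets. Profiles
map classification probabilities to +/- symbol runs:
[0,0.1] ---, (0.1,0.3] --, (0.3,0.5] -, (0.5,0.7] +, (0.7,0.9] ++,
(0.9,1] +++.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors

from .chem_io import MoleculeRecord, canonicalize
from .features import FINGERPRINT_KINDS, compute_fingerprints
from .modeling import ConsensusModel, TrainedModel, predict

RANGE_KEYS = ("MW", "AlogP", "HBA", "HBD")
METRICS = ("tanimoto", "dice")

_ENDPOINT_META = Path(__file__).parent / "data" / "endpoints.yaml"


@dataclass
class SimilarityHit:
    entry_id: str
    score: float
    metric: str
    fingerprint: str


@dataclass
class AdmetRecordStore:
    """In-memory view of a local ADMET record CSV."""

    table: pd.DataFrame
    _fp_cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_csv(cls, path) -> "AdmetRecordStore":
        df = pd.read_csv(path, dtype={"cas": str})
        if "smiles" not in df.columns or "id" not in df.columns:
            raise ValueError("store CSV needs 'id' and 'smiles' columns")
        df = df.copy()
        df["smiles"] = [canonicalize(s) for s in df["smiles"]]
        mols = [Chem.MolFromSmiles(s) for s in df["smiles"]]
        fillers = {
            "MW": lambda m: Descriptors.MolWt(m),
            "AlogP": lambda m: Descriptors.MolLogP(m),
            "HBA": lambda m: rdMolDescriptors.CalcNumHBA(m),
            "HBD": lambda m: rdMolDescriptors.CalcNumHBD(m),
        }
        for col, fn in fillers.items():
            if col not in df.columns:
                df[col] = [fn(m) for m in mols]
            else:
                missing = df[col].isna()
                if missing.any():
                    df.loc[missing, col] = [fn(mols[i]) for i in np.where(missing)[0]]
        for col in ("cas", "iupac_name", "class", "subclass", "reference"):
            if col not in df.columns:
                df[col] = ""
        return cls(df)

    def records(self) -> list[MoleculeRecord]:
        return [
            MoleculeRecord(id=str(r["id"]), smiles=r["smiles"], structure=Chem.MolFromSmiles(r["smiles"]))
            for _, r in self.table.iterrows()
        ]

    def fingerprints(self, kind: str) -> np.ndarray:
        if kind not in self._fp_cache:
            fm = compute_fingerprints(self.records(), kind)
            self._fp_cache[kind] = fm.values.astype(bool)
        return self._fp_cache[kind]


def accurate_search(store: AdmetRecordStore, key_type: str, key: str) -> pd.DataFrame:
    """Exact lookup by canonical SMILES, CAS number or IUPAC name."""
    df = store.table
    if key_type == "smiles":
        mask = df["smiles"] == canonicalize(key)
    elif key_type == "cas":
        mask = df["cas"].astype(str).str.lower() == key.lower()
    elif key_type == "iupac":
        mask = df["iupac_name"].astype(str).str.lower() == key.lower()
    else:
        raise ValueError(f"unknown key_type {key_type!r}; choose smiles, cas or iupac")
    return df[mask].copy()


def range_search(store: AdmetRecordStore, ranges: Mapping[str, tuple[float, float]]) -> pd.DataFrame:
    """Conjunction of inclusive bounds over MW / AlogP / HBA / HBD."""
    if not ranges:
        raise ValueError("at least one range is required")
    mask = np.ones(len(store.table), dtype=bool)
    for key, (lo, hi) in ranges.items():
        if key not in RANGE_KEYS:
            raise ValueError(f"unknown range key {key!r}; choose from {RANGE_KEYS}")
        if lo > hi:
            raise ValueError(f"range for {key}: lo {lo} > hi {hi}")
        col = store.table[key].astype(float)
        mask &= (col >= lo) & (col <= hi)
    return store.table[mask].copy()


def bitset_similarity(a: np.ndarray, b: np.ndarray, metric: str) -> float:
    """Tanimoto or Dice on boolean bit vectors; empty pairs score 0."""
    inter = int(np.logical_and(a, b).sum())
    ca, cb = int(a.sum()), int(b.sum())
    if metric == "tanimoto":
        union = ca + cb - inter
        return inter / union if union else 0.0
    if metric == "dice":
        return 2 * inter / (ca + cb) if (ca + cb) else 0.0
    raise ValueError(f"unknown metric {metric!r}")


def similarity_search(
    store: AdmetRecordStore,
    query: MoleculeRecord,
    fingerprint: str = "ecfp4",
    metric: str = "tanimoto",
    min_score: float | None = None,
    top_k: int | None = None,
) -> list[SimilarityHit]:
    """Rank store entries by fingerprint similarity to the query."""
    if fingerprint not in FINGERPRINT_KINDS:
        raise ValueError(f"unknown fingerprint {fingerprint!r}")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    qfm = compute_fingerprints([query], fingerprint)
    qbits = qfm.values[0].astype(bool)
    if not qbits.any():
        warnings.warn("query fingerprint has no bits set; all scores are 0")
    sbits = store.fingerprints(fingerprint)
    hits = [
        SimilarityHit(
            entry_id=str(store.table.iloc[i]["id"]),
            score=bitset_similarity(qbits, sbits[i], metric) if qbits.any() else 0.0,
            metric=metric,
            fingerprint=fingerprint,
        )
        for i in range(len(store.table))
    ]
    hits.sort(key=lambda h: (-h.score, h.entry_id))
    if min_score is not None:
        hits = [h for h in hits if h.score >= min_score]
    if top_k is not None:
        hits = hits[:top_k]
    return hits


# ---------------------------------------------------------------------------
# systematic profile

_SYMBOL_BANDS = [
    (0.0, 0.1, "---"),
    (0.1, 0.3, "--"),
    (0.3, 0.5, "-"),
    (0.5, 0.7, "+"),
    (0.7, 0.9, "++"),
    (0.9, 1.0, "+++"),
]


def probability_symbol(p: float) -> str:
    """Map a classification probability to its +/- symbol run."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("probability must be in [0, 1]")
    if p <= 0.1:
        return "---"
    for lo, hi, sym in _SYMBOL_BANDS[1:]:
        if lo < p <= hi:
            return sym
    return "+++"


def _endpoint_metadata() -> dict:
    if _ENDPOINT_META.exists():
        with open(_ENDPOINT_META) as fh:
            return yaml.safe_load(fh) or {}
    return {}


@dataclass
class ProfileRow:
    endpoint: str
    predicted: float | None
    unit: str | None
    probability: float | None
    symbol: str | None
    suggestion: str
    reference: str
    failed: bool = False


def systematic_profile(
    record: MoleculeRecord,
    registry: Mapping[str, TrainedModel | ConsensusModel],
    featurizers: Mapping[str, callable] | None = None,
) -> list[ProfileRow]:
    """One profile row per registered endpoint model.

    ``featurizers`` maps endpoint name to a function turning the record into
    the model's FeatureMatrix (defaults to ECFP4 fingerprints for every
    endpoint). A feature mismatch flags the row FAILED instead of aborting
    the profile.
    """
    if not registry:
        raise ValueError("registry must contain at least one endpoint model")
    meta = _endpoint_metadata()
    rows: list[ProfileRow] = []
    for endpoint, model in registry.items():
        info = meta.get(endpoint, {})
        suggestion = info.get("suggestion", "")
        reference = info.get("reference", "")
        unit = info.get("unit")
        try:
            if featurizers and endpoint in featurizers:
                fm = featurizers[endpoint](record)
            else:
                fm = compute_fingerprints([record], "ecfp4")
            preds = predict(model, fm)
        except Exception:
            rows.append(ProfileRow(endpoint, None, unit, None, None, suggestion, reference, failed=True))
            continue
        if model.task == "regression":
            rows.append(
                ProfileRow(endpoint, float(preds["value"][0]), unit, None, None, suggestion, reference)
            )
        else:
            p = float(preds["probability"][0])
            rows.append(
                ProfileRow(endpoint, None, unit, p, probability_symbol(p), suggestion, reference)
            )
    return rows


def profile_table(rows: Sequence[ProfileRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "endpoint": r.endpoint,
                "predicted": r.predicted,
                "unit": r.unit,
                "probability": r.probability,
                "symbol": r.symbol,
                "suggestion": r.suggestion,
                "reference": r.reference,
                "failed": r.failed,
            }
            for r in rows
        ]
    )
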