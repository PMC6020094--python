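"""Dataset pretreatments and the diverse 75/25 train/test split.

Duplicate handling mirrors the platform's rules: classification duplicates
collapse to a single entry when their labels agree and are dropped on
conflict; regression duplicates are replaced by their arithmetic mean when
the relative spread is within a configurable limit and deleted otherwise.
The split selects a maximally diverse training set by max-min (Kennard-Stone
style) picking on Tanimoto distance over ECFP4 bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem_io import MoleculeRecord
from .features import FeatureMatrix, compute_fingerprints

NO_EXPLICIT_VALUE = "NO_EXPLICIT_VALUE"
CONFLICTING_LABELS = "CONFLICTING_LABELS"
EXCESS_SPREAD = "EXCESS_SPREAD"


@dataclass
class LabeledDataset:
    """Feature matrix plus endpoint labels."""

    features: FeatureMatrix
    y: np.ndarray
    endpoint: str = "endpoint"
    task: str = "regression"

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if len(self.y) != self.features.n:
            raise ValueError("y length must equal feature row count")
        if self.task == "classification" and not set(np.unique(self.y)) <= {0.0, 1.0}:
            raise ValueError("classification labels must be 0/1")

    @property
    def n(self) -> int:
        return self.features.n

    def subset(self, ids: Sequence[str]) -> "LabeledDataset":
        idx = [self.features.row_ids.index(i) for i in ids]
        return LabeledDataset(self.features.subset_rows(ids), self.y[idx], self.endpoint, self.task)


@dataclass
class SplitResult:
    train_ids: list[str]
    test_ids: list[str]
    fraction: float
    seed: int


@dataclass
class AggregationReport:
    merged: list[tuple[str, int, float]] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)


def deduplicate_classification(
    records: Sequence[MoleculeRecord], labels: Sequence[float]
) -> tuple[list[MoleculeRecord], np.ndarray, AggregationReport]:
    """Collapse duplicate structures; drop groups with conflicting labels."""
    labels = np.asarray(labels, dtype=float)
    if not set(np.unique(labels)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(rec.smiles, []).append(i)
    out_records, out_labels = [], []
    report = AggregationReport()
    for smi, idxs in groups.items():
        grp = {labels[i] for i in idxs}
        if len(grp) > 1:
            report.dropped.append((smi, CONFLICTING_LABELS))
            continue
        if len(idxs) > 1:
            report.merged.append((smi, len(idxs), labels[idxs[0]]))
        out_records.append(records[idxs[0]])
        out_labels.append(labels[idxs[0]])
    return out_records, np.asarray(out_labels), report


def aggregate_regression(
    records: Sequence[MoleculeRecord],
    values: Sequence[float],
    rel_spread_limit: float = 0.5,
    abs_eps: float = 1e-8,
) -> tuple[list[MoleculeRecord], np.ndarray, AggregationReport]:
    """Merge duplicate structures by arithmetic mean when their relative
    spread (max-min)/|mean| stays within *rel_spread_limit*; delete otherwise.

    When the group mean is exactly 0, the absolute range is tested against
    *abs_eps* instead.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(rec.smiles, []).append(i)
    out_records, out_values = [], []
    report = AggregationReport()
    for smi, idxs in groups.items():
        vals = values[idxs]
        if len(idxs) == 1:
            out_records.append(records[idxs[0]])
            out_values.append(float(vals[0]))
            continue
        mean = float(vals.mean())
        spread = float(vals.max() - vals.min())
        ok = spread <= abs_eps if mean == 0.0 else spread / abs(mean) <= rel_spread_limit
        if ok:
            out_records.append(records[idxs[0]])
            out_values.append(mean)
            report.merged.append((smi, len(idxs), mean))
        else:
            report.dropped.append((smi, EXCESS_SPREAD))
    return out_records, np.asarray(out_values), report


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def tanimoto_distance_matrix(bits: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Tanimoto over a 0/1 bit matrix."""
    b = bits.astype(np.float64)
    inter = b @ b.T
    counts = b.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    return 1.0 - sim


def diverse_split(
    features: FeatureMatrix | Sequence[MoleculeRecord],
    fraction: float = 0.75,
    seed: int = 0,
) -> SplitResult:
    """Partition molecules into train/test by max-min diversity picking.

    The first pick is the molecule with the highest mean Tanimoto distance
    to all others; each further pick maximizes the minimum distance to the
    already-picked set. |train| = round(fraction * n), rounding half up.
    The seed only breaks exact distance ties.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if isinstance(features, FeatureMatrix):
        fm = features
        if fm.kind != "fingerprint":
            # descriptor matrices are binarized per-column at the median for
            # the distance computation only
            med = np.median(fm.values, axis=0)
            bits = (fm.values > med).astype(np.int8)
        else:
            bits = fm.values
        ids = fm.row_ids
    else:
        fm = compute_fingerprints(features, "ecfp4")
        bits = fm.values
        ids = fm.row_ids
    n = len(ids)
    if n < 4:
        raise ValueError("too few molecules to split (need n >= 4)")
    n_train = min(max(_round_half_up(fraction * n), 1), n - 1)

    dist = tanimoto_distance_matrix(np.asarray(bits))
    rng = np.random.default_rng(seed)
    jitter = rng.random(n) * 1e-12  # deterministic tie-break
    order_key = dist.mean(axis=1) + jitter
    picked = [int(np.argmax(order_key))]
    min_dist = dist[picked[0]].copy()
    min_dist[picked[0]] = -np.inf
    while len(picked) < n_train:
        nxt = int(np.argmax(min_dist + jitter))
        picked.append(nxt)
        min_dist = np.minimum(min_dist, dist[nxt])
        min_dist[nxt] = -np.inf
    train_ids = [ids[i] for i in sorted(picked)]
    test_ids = [ids[i] for i in range(n) if i not in set(picked)]
    return SplitResult(train_ids, test_ids, fraction, seed)
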