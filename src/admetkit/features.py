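"""Molecular descriptors and fingerprints as feature matrices.

Eleven descriptor families (constitution, topology, connectivity, E-state,
kappa, Basak information indices, Burden/BCUT, autocorrelation, charge,
molecular property, MOE-type surface areas) computed with RDKit, plus five
fingerprints: FP2 (hashed linear paths up to 7 atoms, 2048 bits), MACCS
(167 keys) and ECFP2/4/6 (circular, radius 1/2/3, folded to 2048 bits).

The family manifest below is the membership contract; per-family column
counts follow the conventional layout where RDKit supports it (the property
family is exactly 6 columns: LogP, molar refractivity, TPSA, H-bond donors,
H-bond acceptors, molecular weight).
"""

from __future__ import annotations

import math
import zlib
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors, GraphDescriptors, MACCSkeys, rdMolDescriptors
from rdkit.Chem.EState import EState

from .chem_io import MoleculeRecord

FINGERPRINT_KINDS = ("fp2", "maccs", "ecfp2", "ecfp4", "ecfp6")
FINGERPRINT_WIDTHS = {"fp2": 2048, "maccs": 167, "ecfp2": 2048, "ecfp4": 2048, "ecfp6": 2048}
ECFP_RADIUS = {"ecfp2": 1, "ecfp4": 2, "ecfp6": 3}

DESCRIPTOR_FAMILIES = (
    "constitution",
    "topology",
    "connectivity",
    "estate",
    "kappa",
    "basak",
    "burden",
    "autocorrelation",
    "charge",
    "property",
    "moe_type",
)


@dataclass
class FeatureMatrix:
    """Molecules x named features.

    ``kind`` is ``descriptor`` (continuous) or ``fingerprint`` (0/1 bits);
    ``family`` tags every column with its descriptor family or fingerprint
    kind. ``failures`` lists (molecule id, reason) for molecules excluded
    before assembly; the assembled grid never contains missing cells.
    """

    df: pd.DataFrame
    kind: str
    family: pd.Series
    failures: list[tuple[str, str]] = field(default_factory=list)

    @property
    def row_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def p(self) -> int:
        return self.df.shape[1]

    @property
    def n(self) -> int:
        return self.df.shape[0]

    def subset_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        names = list(names)
        return FeatureMatrix(self.df[names].copy(), self.kind, self.family[names].copy(), list(self.failures))

    def subset_rows(self, ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.df.loc[list(ids)].copy(), self.kind, self.family.copy(), list(self.failures))

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "id", out.index)
        out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# descriptor family manifest


def _bond_counts(mol):
    single = double = triple = aromatic = 0
    for b in mol.GetBonds():
        t = b.GetBondType()
        if b.GetIsAromatic() or t == Chem.BondType.AROMATIC:
            aromatic += 1
        elif t == Chem.BondType.SINGLE:
            single += 1
        elif t == Chem.BondType.DOUBLE:
            double += 1
        elif t == Chem.BondType.TRIPLE:
            triple += 1
    return single, double, triple, aromatic


def _element_count(mol, z):
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == z)


def _constitution(mol) -> dict[str, float]:
    single, double, triple, aromatic = _bond_counts(mol)
    molh = Chem.AddHs(mol)
    d = {
        "MolWt": Descriptors.MolWt(mol),
        "HeavyAtomMolWt": Descriptors.HeavyAtomMolWt(mol),
        "nHeavy": mol.GetNumHeavyAtoms(),
        "nH": _element_count(molh, 1),
        "nC": _element_count(mol, 6),
        "nN": _element_count(mol, 7),
        "nO": _element_count(mol, 8),
        "nS": _element_count(mol, 16),
        "nP": _element_count(mol, 15),
        "nF": _element_count(mol, 9),
        "nCl": _element_count(mol, 17),
        "nBr": _element_count(mol, 35),
        "nI": _element_count(mol, 53),
        "nHet": Descriptors.NumHeteroatoms(mol),
        "nBonds": mol.GetNumBonds(),
        "nBondsS": single,
        "nBondsD": double,
        "nBondsT": triple,
        "nBondsAro": aromatic,
        "nRing": rdMolDescriptors.CalcNumRings(mol),
        "nAroRing": rdMolDescriptors.CalcNumAromaticRings(mol),
        "nSatRing": rdMolDescriptors.CalcNumSaturatedRings(mol),
        "nAliRing": rdMolDescriptors.CalcNumAliphaticRings(mol),
        "nRotB": Descriptors.NumRotatableBonds(mol),
        "nHBD": rdMolDescriptors.CalcNumHBD(mol),
        "nHBA": rdMolDescriptors.CalcNumHBA(mol),
        "nSpiro": rdMolDescriptors.CalcNumSpiroAtoms(mol),
        "nBridgehead": rdMolDescriptors.CalcNumBridgeheadAtoms(mol),
        "FractionCSP3": Descriptors.FractionCSP3(mol),
        "FormalCharge": Chem.GetFormalCharge(mol),
    }
    return d


def _topology(mol) -> dict[str, float]:
    n = mol.GetNumHeavyAtoms()
    dmat = Chem.GetDistanceMatrix(mol) if n > 1 else np.zeros((1, 1))
    finite = dmat[np.isfinite(dmat)]
    wiener = float(finite.sum() / 2)
    ecc = np.where(np.isfinite(dmat), dmat, 0).max(axis=1) if n > 0 else np.array([0.0])
    diameter = float(ecc.max()) if n else 0.0
    radius = float(ecc.min()) if n else 0.0
    petitjean = (diameter - radius) / radius if radius > 0 else 0.0
    degs = [a.GetDegree() for a in mol.GetAtoms()]
    zagreb1 = float(sum(d * d for d in degs))
    zagreb2 = float(
        sum(b.GetBeginAtom().GetDegree() * b.GetEndAtom().GetDegree() for b in mol.GetBonds())
    )
    return {
        "Wiener": wiener,
        "BalabanJ": Descriptors.BalabanJ(mol),
        "BertzCT": Descriptors.BertzCT(mol),
        "AvgIpc": GraphDescriptors.AvgIpc(mol),
        "Zagreb1": zagreb1,
        "Zagreb2": zagreb2,
        "Diameter": diameter,
        "Radius": radius,
        "Petitjean": petitjean,
    }


_CHI_NAMES = ["Chi0", "Chi1", "Chi0n", "Chi1n", "Chi2n", "Chi3n", "Chi4n", "Chi0v", "Chi1v", "Chi2v", "Chi3v", "Chi4v"]


def _connectivity(mol) -> dict[str, float]:
    return {name: getattr(Descriptors, name)(mol) for name in _CHI_NAMES}


def _estate(mol) -> dict[str, float]:
    d = {f"EState_VSA{i}": getattr(Descriptors, f"EState_VSA{i}")(mol) for i in range(1, 12)}
    d.update({f"VSA_EState{i}": getattr(Descriptors, f"VSA_EState{i}")(mol) for i in range(1, 11)})
    indices = EState.EStateIndices(mol) if mol.GetNumHeavyAtoms() else [0.0]
    d["MaxEStateIndex"] = float(max(indices))
    d["MinEStateIndex"] = float(min(indices))
    d["SumEStateIndex"] = float(sum(indices))
    return d


def _kappa(mol) -> dict[str, float]:
    k1, k3 = Descriptors.Kappa1(mol), Descriptors.Kappa3(mol)
    n = max(mol.GetNumHeavyAtoms(), 1)
    return {
        "Kappa1": k1,
        "Kappa2": Descriptors.Kappa2(mol),
        "Kappa3": k3,
        "HallKierAlpha": Descriptors.HallKierAlpha(mol),
        "KierFlex": k1 * k3 / n,
    }


def _atom_classes(mol, order: int) -> Counter:
    """Equivalence classes for information indices: atom environment strings
    out to *order* bonds."""
    classes = Counter()
    for atom in mol.GetAtoms():
        env = [(atom.GetAtomicNum(), atom.GetDegree(), atom.GetTotalNumHs())]
        frontier = {atom.GetIdx()}
        seen = set(frontier)
        for _ in range(order):
            nxt = set()
            shell = []
            for idx in frontier:
                for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
                    if nb.GetIdx() not in seen:
                        shell.append((nb.GetAtomicNum(), nb.GetDegree(), nb.GetTotalNumHs()))
                        nxt.add(nb.GetIdx())
            seen |= nxt
            frontier = nxt
            env.append(tuple(sorted(shell)))
        classes[tuple(env)] += 1
    return classes


def _basak(mol) -> dict[str, float]:
    """Shannon information-content indices on atom neighborhoods of order
    0, 1 and 2 (IC, structural SIC, complementary CIC)."""
    n = mol.GetNumHeavyAtoms()
    out = {}
    for order in (0, 1, 2):
        counts = _atom_classes(mol, order)
        total = sum(counts.values())
        if total <= 1:
            ic = 0.0
        else:
            probs = [c / total for c in counts.values()]
            ic = -sum(p * math.log2(p) for p in probs)
        log_n = math.log2(total) if total > 1 else 1.0
        out[f"IC{order}"] = ic
        out[f"SIC{order}"] = ic / log_n if log_n else 0.0
        out[f"CIC{order}"] = log_n - ic
    return out


_BCUT_NAMES = [
    "BCUT2D_MWHI", "BCUT2D_MWLOW", "BCUT2D_CHGHI", "BCUT2D_CHGLO",
    "BCUT2D_LOGPHI", "BCUT2D_LOGPLOW", "BCUT2D_MRHI", "BCUT2D_MRLOW",
]


def _burden(mol) -> dict[str, float]:
    vals = rdMolDescriptors.BCUT2D(mol)
    return dict(zip(_BCUT_NAMES, vals))


def _gasteiger(mol) -> np.ndarray:
    m = Chem.Mol(mol)
    AllChem.ComputeGasteigerCharges(m)
    return np.array([float(a.GetProp("_GasteigerCharge")) for a in m.GetAtoms()])


def _autocorrelation(mol) -> dict[str, float]:
    """Moreau-Broto autocorrelation (ATS) over atomic mass and Gasteiger
    charge at topological lags 1..8."""
    n = mol.GetNumHeavyAtoms()
    dmat = Chem.GetDistanceMatrix(mol) if n > 1 else np.zeros((1, 1))
    mass = np.array([a.GetMass() for a in mol.GetAtoms()])
    charge = _gasteiger(mol)
    out = {}
    for prop, arr in (("m", mass), ("c", charge)):
        for lag in range(1, 9):
            mask = dmat == lag
            val = float((np.outer(arr, arr)[mask]).sum() / 2) if mask.any() else 0.0
            out[f"ATS{prop}{lag}"] = math.log1p(abs(val)) * math.copysign(1, val) if prop == "m" else val
    return out


def _charge(mol) -> dict[str, float]:
    q = _gasteiger(mol)
    pos, neg = q[q > 0], q[q < 0]
    tot_pos = float(pos.sum()) if pos.size else 0.0
    tot_neg = float(neg.sum()) if neg.size else 0.0
    tot_abs = float(np.abs(q).sum())
    return {
        "QMax": float(q.max()) if q.size else 0.0,
        "QMin": float(q.min()) if q.size else 0.0,
        "QMaxAbs": float(np.abs(q).max()) if q.size else 0.0,
        "QTotPos": tot_pos,
        "QTotNeg": tot_neg,
        "QTotAbs": tot_abs,
        "QRelPos": tot_pos / tot_abs if tot_abs else 0.0,
        "QRelNeg": abs(tot_neg) / tot_abs if tot_abs else 0.0,
        "QMean": float(q.mean()) if q.size else 0.0,
    }


def _property(mol) -> dict[str, float]:
    # exactly six molecular-property descriptors
    return {
        "LogP": Descriptors.MolLogP(mol),
        "MR": Descriptors.MolMR(mol),
        "TPSA": Descriptors.TPSA(mol),
        "HBD": float(rdMolDescriptors.CalcNumHBD(mol)),
        "HBA": float(rdMolDescriptors.CalcNumHBA(mol)),
        "MW": Descriptors.MolWt(mol),
    }


def _moe_type(mol) -> dict[str, float]:
    d = {f"SlogP_VSA{i}": getattr(Descriptors, f"SlogP_VSA{i}")(mol) for i in range(1, 13)}
    d.update({f"SMR_VSA{i}": getattr(Descriptors, f"SMR_VSA{i}")(mol) for i in range(1, 11)})
    d.update({f"PEOE_VSA{i}": getattr(Descriptors, f"PEOE_VSA{i}")(mol) for i in range(1, 15)})
    d["LabuteASA"] = Descriptors.LabuteASA(mol)
    return d


FAMILY_FUNCTIONS: dict[str, Callable] = {
    "constitution": _constitution,
    "topology": _topology,
    "connectivity": _connectivity,
    "estate": _estate,
    "kappa": _kappa,
    "basak": _basak,
    "burden": _burden,
    "autocorrelation": _autocorrelation,
    "charge": _charge,
    "property": _property,
    "moe_type": _moe_type,
}


def family_manifest() -> dict[str, list[str]]:
    """Column names per descriptor family, computed on a probe molecule."""
    probe = Chem.MolFromSmiles("CC(=O)Oc1ccccc1C(=O)O")
    return {fam: list(fn(probe).keys()) for fam, fn in FAMILY_FUNCTIONS.items()}


def compute_descriptors(
    records: Sequence[MoleculeRecord], families: Iterable[str] | None = None
) -> FeatureMatrix:
    """Compute continuous descriptors for the given families.

    Families appear as contiguous column blocks in the declared family order.
    Molecules with any non-finite descriptor value are excluded and listed in
    ``FeatureMatrix.failures``.
    """
    if families is None:
        families = DESCRIPTOR_FAMILIES
    families = [f for f in DESCRIPTOR_FAMILIES if f in set(families)]
    if not families:
        raise ValueError("families must be a non-empty subset of the descriptor families")
    unknown = set(families) - set(DESCRIPTOR_FAMILIES)
    if unknown:
        raise ValueError(f"unknown descriptor families: {sorted(unknown)}")

    rows, ids, failures = [], [], []
    for rec in records:
        # reparse from canonical SMILES: identical structures then yield
        # bit-identical descriptor rows regardless of input atom order
        mol = Chem.MolFromSmiles(rec.smiles) or Chem.RemoveHs(rec.structure)
        row: dict[str, float] = {}
        try:
            for fam in families:
                row.update(FAMILY_FUNCTIONS[fam](mol))
        except Exception as exc:  # descriptor computation failure
            failures.append((rec.id, f"DESCRIPTOR_ERROR: {exc}"))
            continue
        vals = np.array(list(row.values()), dtype=float)
        if not np.all(np.isfinite(vals)):
            failures.append((rec.id, "NON_FINITE_DESCRIPTOR"))
            continue
        rows.append(row)
        ids.append(rec.id)

    df = pd.DataFrame(rows, index=ids, dtype=float)
    fam_tags = {}
    for fam in families:
        for name in family_manifest()[fam]:
            if name in df.columns:
                fam_tags[name] = fam
    family = pd.Series({c: fam_tags.get(c, "unknown") for c in df.columns})
    return FeatureMatrix(df, "descriptor", family, failures)


# ---------------------------------------------------------------------------
# fingerprints


def _fp2_path_bits(mol, n_bits: int = 2048) -> tuple[set[int], set[str]]:
    """Linear-path fragments of 2..7 atoms, canonicalized by direction and
    hashed (CRC32) into *n_bits*; returns folded bit ids and fragment keys."""
    bits: set[int] = set()
    keys: set[str] = set()
    for n_bonds in range(1, 7):  # 2..7 atoms
        for path in Chem.FindAllPathsOfLengthN(mol, n_bonds, useBonds=True):
            atoms: list[int] = []
            bonds = [mol.GetBondWithIdx(b) for b in path]
            # reconstruct the atom sequence along the path
            if len(bonds) == 1:
                atoms = [bonds[0].GetBeginAtomIdx(), bonds[0].GetEndAtomIdx()]
            else:
                first, second = bonds[0], bonds[1]
                shared = {first.GetBeginAtomIdx(), first.GetEndAtomIdx()} & {
                    second.GetBeginAtomIdx(), second.GetEndAtomIdx()
                }
                if not shared:
                    continue
                s = shared.pop()
                atoms = [first.GetOtherAtomIdx(s), s]
                for b in bonds[1:]:
                    atoms.append(b.GetOtherAtomIdx(atoms[-1]))
            def atok(ai):
                a = mol.GetAtomWithIdx(ai)
                return f"{a.GetAtomicNum()}{'a' if a.GetIsAromatic() else ''}"

            def btok(b):
                if b.GetIsAromatic():
                    return "~"
                return {Chem.BondType.SINGLE: "-", Chem.BondType.DOUBLE: "=",
                        Chem.BondType.TRIPLE: "#"}.get(b.GetBondType(), "?")

            distinct = len(set(atoms))
            if atoms[0] == atoms[-1] and distinct == len(atoms) - 1:
                # closed ring walk: the toolkit returns one arbitrary rotation
                # per bond set, so canonicalize over rotations and directions
                cyc_a = [atok(ai) for ai in atoms[:-1]]
                cyc_b = [btok(b) for b in bonds]
                m = len(cyc_a)
                variants = []
                for r in range(m):
                    fwd = []
                    for i in range(m):
                        fwd += [cyc_a[(r + i) % m], cyc_b[(r + i) % m]]
                    fwd.append(cyc_a[r])
                    variants.append("".join(fwd))
                    rev = []
                    for i in range(m):
                        rev += [cyc_a[(r - i) % m], cyc_b[(r - i - 1) % m]]
                    rev.append(cyc_a[r])
                    variants.append("".join(rev))
                key = min(variants)
            elif distinct < len(atoms):
                # walk revisits an atom without being a pure cycle (branch +
                # ring "tadpole"): no orientation-free canonical form, skip
                continue
            else:
                tokens = []
                for i, ai in enumerate(atoms):
                    tokens.append(atok(ai))
                    if i < len(bonds):
                        tokens.append(btok(bonds[i]))
                fwd = "".join(tokens)
                rev = "".join(reversed(tokens))
                key = min(fwd, rev)
            keys.add(key)
            bits.add(zlib.crc32(key.encode()) % n_bits)
    return bits, keys


def fp2_fragment_keys(mol) -> set[str]:
    """Unfolded canonical linear-path fragment identifiers (2..7 atoms)."""
    return _fp2_path_bits(mol)[1]


def ecfp_identifiers(mol, radius: int) -> set[int]:
    """Unfolded circular-substructure identifiers up to *radius*."""
    fp = AllChem.GetMorganFingerprint(mol, radius)
    return set(fp.GetNonzeroElements().keys())


def _fingerprint_row(mol, kind: str) -> np.ndarray:
    width = FINGERPRINT_WIDTHS[kind]
    row = np.zeros(width, dtype=np.int8)
    if kind == "maccs":
        fp = MACCSkeys.GenMACCSKeys(mol)
        row[list(fp.GetOnBits())] = 1
    elif kind == "fp2":
        bits, _ = _fp2_path_bits(mol, width)
        row[list(bits)] = 1
    else:
        fp = AllChem.GetMorganFingerprintAsBitVect(mol, ECFP_RADIUS[kind], nBits=width)
        row[list(fp.GetOnBits())] = 1
    return row


def compute_fingerprints(records: Sequence[MoleculeRecord], kind: str) -> FeatureMatrix:
    """Bit-matrix fingerprints of the requested kind (fixed width per kind)."""
    if kind not in FINGERPRINT_KINDS:
        raise ValueError(f"unknown fingerprint kind: {kind!r}; choose from {FINGERPRINT_KINDS}")
    rows, ids, failures = [], [], []
    for rec in records:
        mol = Chem.RemoveHs(rec.structure)
        try:
            rows.append(_fingerprint_row(mol, kind))
            ids.append(rec.id)
        except Exception as exc:
            failures.append((rec.id, f"FINGERPRINT_ERROR: {exc}"))
    width = FINGERPRINT_WIDTHS[kind]
    cols = [f"{kind}_{i}" for i in range(width)]
    df = pd.DataFrame(np.array(rows, dtype=np.int8).reshape(len(rows), width), index=ids, columns=cols)
    family = pd.Series({c: kind for c in cols})
    return FeatureMatrix(df, "fingerprint", family, failures)
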