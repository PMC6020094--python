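"""Drug-likeness rule batteries: Lipinski, Ghose, Oprea, Veber and Varma.

Thresholds follow the canonical published forms and live in a plain config
structure so they can be overridden without code changes (Lipinski allows one
violation; the others none). Every criterion is evaluated and reported — no
short-circuiting — and descriptor failures yield an INCOMPUTABLE flag rather
than a silent pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors

from .chem_io import MoleculeRecord

RULE_NAMES = ("lipinski", "ghose", "oprea", "veber", "varma")


def rule_descriptors(mol) -> dict[str, float]:
    """The simple descriptors the five rule batteries reference."""
    return {
        "MW": Descriptors.MolWt(mol),
        "LogP": Descriptors.MolLogP(mol),
        "HBD": float(rdMolDescriptors.CalcNumHBD(mol)),
        "HBA": float(rdMolDescriptors.CalcNumHBA(mol)),
        "MR": Descriptors.MolMR(mol),
        "AtomCount": float(Chem.AddHs(mol).GetNumAtoms()),
        "Rings": float(rdMolDescriptors.CalcNumRings(mol)),
        "RotB": float(Descriptors.NumRotatableBonds(mol)),
        "TPSA": Descriptors.TPSA(mol),
    }


@dataclass
class RuleDefinition:
    name: str
    # criterion: (descriptor, comparator in {"<=", ">=", "range"}, bounds)
    criteria: list[tuple[str, str, tuple]]
    max_violations: int = 0


@dataclass
class RuleResult:
    molecule_id: str
    rule: str
    criteria: list[dict] = field(default_factory=list)
    n_violations: int = 0
    overall_pass: bool = False
    incomputable: bool = False


DEFAULT_RULES: dict[str, RuleDefinition] = {
    "lipinski": RuleDefinition(
        "lipinski",
        [("MW", "<=", (500,)), ("LogP", "<=", (5,)), ("HBD", "<=", (5,)), ("HBA", "<=", (10,))],
        max_violations=1,
    ),
    "ghose": RuleDefinition(
        "ghose",
        [
            ("MW", "range", (160, 480)),
            ("LogP", "range", (-0.4, 5.6)),
            ("MR", "range", (40, 130)),
            ("AtomCount", "range", (20, 70)),
        ],
    ),
    "oprea": RuleDefinition(
        "oprea",
        [
            ("MW", "<=", (450,)),
            ("LogP", "<=", (4.5,)),
            ("Rings", "<=", (4,)),
            ("RotB", "<=", (10,)),
            ("HBD", "<=", (5,)),
            ("HBA", "<=", (8,)),
        ],
    ),
    "veber": RuleDefinition("veber", [("RotB", "<=", (10,)), ("TPSA", "<=", (140,))]),
    "varma": RuleDefinition(
        "varma",
        [("MW", "<=", (500,)), ("TPSA", "<=", (125,)), ("LogP", "<=", (5,))],
    ),
}


def _check(value: float, comparator: str, bounds: tuple) -> bool:
    if comparator == "<=":
        return value <= bounds[0]
    if comparator == ">=":
        return value >= bounds[0]
    if comparator == "range":
        return bounds[0] <= value <= bounds[1]
    raise ValueError(f"unknown comparator {comparator!r}")


def evaluate_rule(record: MoleculeRecord, rule: RuleDefinition) -> RuleResult:
    """Evaluate one rule battery on one washed molecule."""
    result = RuleResult(molecule_id=record.id, rule=rule.name)
    try:
        mol = Chem.RemoveHs(record.structure)
        desc = rule_descriptors(mol)
    except Exception:
        result.incomputable = True
        return result
    for name, comparator, bounds in rule.criteria:
        value = desc[name]
        ok = _check(value, comparator, bounds)
        result.criteria.append(
            {"descriptor": name, "value": value, "comparator": comparator, "bounds": bounds, "pass": ok}
        )
        if not ok:
            result.n_violations += 1
    result.overall_pass = result.n_violations <= rule.max_violations
    return result


def evaluate_all(
    records: Sequence[MoleculeRecord], rules: dict[str, RuleDefinition] | None = None
) -> list[RuleResult]:
    """All rule batteries for all molecules (five results per molecule)."""
    rules = rules or DEFAULT_RULES
    return [evaluate_rule(rec, rules[name]) for rec in records for name in RULE_NAMES if name in rules]


def results_table(results: Sequence[RuleResult]) -> pd.DataFrame:
    rows = [
        {
            "id": r.molecule_id,
            "rule": r.rule,
            "n_violations": r.n_violations,
            "overall_pass": r.overall_pass,
            "incomputable": r.incomputable,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def load_rule_overrides(path) -> dict[str, RuleDefinition]:
    """Apply ``rule.descriptor = bound`` overrides from a key=value file.

    A single number rebinds a ``<=`` / ``>=`` criterion; ``lo:hi`` rebinds a
    range criterion.
    """
    import copy

    rules = copy.deepcopy(DEFAULT_RULES)
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        rule_name, _, desc = key.strip().partition(".")
        if rule_name not in rules:
            raise ValueError(f"unknown rule {rule_name!r}")
        value = value.strip()
        hit = False
        for i, (name, comparator, bounds) in enumerate(rules[rule_name].criteria):
            if name == desc:
                if comparator == "range":
                    lo, _, hi = value.partition(":")
                    rules[rule_name].criteria[i] = (name, comparator, (float(lo), float(hi)))
                else:
                    rules[rule_name].criteria[i] = (name, comparator, (float(value),))
                hit = True
        if not hit:
            raise ValueError(f"rule {rule_name!r} has no criterion on {desc!r}")
    return rules

# The platform's drug-likeness classifier is a preset recipe: a random
# forest on MACCS keys; training data (DrugBank positives / ChEMBL
# negatives) must be supplied by the user.
DRUGLIKENESS_MODEL_RECIPE = {
    "fingerprint": "maccs",
    "algorithm": "rf",
    "task": "classification",
    "hyperparameters": {"estimators": 500},
}
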