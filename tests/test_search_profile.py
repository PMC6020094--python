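import numpy as np
import pandas as pd
import pytest

import admetkit as ak
from admetkit.chem_io import record_from_smiles
from admetkit.features import FINGERPRINT_KINDS
from admetkit.modeling import ModelConfig, train
from admetkit.search_profile import (
    AdmetRecordStore,
    accurate_search,
    bitset_similarity,
    probability_symbol,
    profile_table,
    range_search,
    similarity_search,
    systematic_profile,
)


@pytest.fixture()
def store(store_csv):
    return AdmetRecordStore.from_csv(store_csv)


class TestAccurateSearch:
    def test_smiles_matched_by_canonical_form(self, store, corpus):
        # query an alternative SMILES spelling of a stored entry
        from rdkit import Chem

        mol = Chem.MolFromSmiles(corpus[0].smiles)
        alt = Chem.MolToSmiles(mol, canonical=False, doRandom=False)
        hits = accurate_search(store, "smiles", alt)
        assert list(hits["id"]) == [corpus[0].id]

    def test_absent_cas_empty_not_error(self, store):
        assert len(accurate_search(store, "cas", "999-99-9")) == 0

    def test_iupac_case_insensitive(self, store):
        hits = accurate_search(store, "iupac", "synthetic compound 3")
        assert len(hits) == 1

    def test_unknown_key_type(self, store):
        with pytest.raises(ValueError):
            accurate_search(store, "inchi", "x")


class TestRangeSearch:
    def test_counting_toy_store(self, tmp_path):
        df = pd.DataFrame(
            {"id": list("abcde"), "smiles": ["CCO"] * 5, "MW": [100, 200, 300, 400, 500]}
        )
        p = tmp_path / "toy.csv"
        df.to_csv(p, index=False)
        store = AdmetRecordStore.from_csv(p)
        # stored MW column is respected over the computed value
        assert len(range_search(store, {"MW": (150, 350)})) == 2
        assert len(range_search(store, {"MW": (200, 300)})) == 2  # inclusive bounds

    def test_conjunction(self, store):
        wide = range_search(store, {"MW": (0, 1000)})
        both = range_search(store, {"MW": (0, 1000), "HBD": (1, 10)})
        assert set(both["id"]) <= set(wide["id"])

    def test_bad_inputs(self, store):
        with pytest.raises(ValueError):
            range_search(store, {})
        with pytest.raises(ValueError):
            range_search(store, {"MW": (300, 100)})


class TestSimilarity:
    @pytest.mark.parametrize("kind", FINGERPRINT_KINDS)
    @pytest.mark.parametrize("metric", ["tanimoto", "dice"])
    def test_self_similarity_is_one(self, store, corpus, kind, metric):
        hits = similarity_search(store, corpus[0], kind, metric, top_k=1)
        assert hits[0].score == 1.0

    def test_sorted_descending_with_id_ties(self, store, corpus):
        hits = similarity_search(store, corpus[5], "maccs", "tanimoto")
        scores = [h.score for h in hits]
        assert scores == sorted(scores, reverse=True)
        for a, b in zip(hits, hits[1:]):
            if a.score == b.score:
                assert a.entry_id < b.entry_id

    def test_brute_force_oracle_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            a = rng.integers(0, 2, 64).astype(bool)
            b = rng.integers(0, 2, 64).astype(bool)
            sa, sb = set(np.where(a)[0]), set(np.where(b)[0])
            inter = len(sa & sb)
            union = len(sa | sb)
            tan = inter / union if union else 0.0
            dice = 2 * inter / (len(sa) + len(sb)) if (sa or sb) else 0.0
            assert bitset_similarity(a, b, "tanimoto") == pytest.approx(tan, abs=1e-12)
            assert bitset_similarity(a, b, "dice") == pytest.approx(dice, abs=1e-12)

    def test_tanimoto_le_dice(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a = rng.integers(0, 2, 32).astype(bool)
            b = rng.integers(0, 2, 32).astype(bool)
            if not (a & b).any():
                continue
            assert bitset_similarity(a, b, "tanimoto") <= bitset_similarity(a, b, "dice")

    def test_disjoint_bitsets_zero(self):
        a = np.array([1, 1, 0, 0], dtype=bool)
        b = np.array([0, 0, 1, 1], dtype=bool)
        assert bitset_similarity(a, b, "tanimoto") == 0.0
        assert bitset_similarity(a, b, "dice") == 0.0

    def test_min_score_filter(self, store, corpus):
        hits = similarity_search(store, corpus[0], "ecfp4", "tanimoto", min_score=0.99)
        assert all(h.score >= 0.99 for h in hits)


class TestProfile:
    @pytest.fixture()
    def registry(self, corpus):
        fm = ak.compute_fingerprints(corpus[:30], "ecfp4")
        y = (np.arange(30) % 2).astype(float)
        ds = ak.LabeledDataset(fm, y, task="classification")
        clf = train(ds, ModelConfig("rf", "classification", {"estimators": 20}, seed=0))
        dfr = ak.LabeledDataset(fm, np.linspace(-3, 1, 30), task="regression")
        reg = train(dfr, ModelConfig("rf", "regression", {"estimators": 20}, seed=0))
        return {"bbb": clf, "herg": clf, "logS": reg}

    @pytest.mark.parametrize(
        "p,symbol",
        [(0.05, "---"), (0.1, "---"), (0.2, "--"), (0.4, "-"), (0.6, "+"), (0.8, "++"), (0.95, "+++")],
    )
    def test_symbol_bands(self, p, symbol):
        assert probability_symbol(p) == symbol

    def test_one_row_per_endpoint(self, corpus, registry):
        rows = systematic_profile(corpus[0], registry)
        assert len(rows) == 3
        table = profile_table(rows)
        assert set(table["endpoint"]) == {"bbb", "herg", "logS"}

    def test_classification_rows_have_symbols(self, corpus, registry):
        rows = systematic_profile(corpus[0], registry)
        for r in rows:
            if r.probability is not None:
                assert r.symbol in {"---", "--", "-", "+", "++", "+++"}
                assert 0 <= r.probability <= 1
            else:
                assert r.symbol is None

    def test_failed_endpoint_flagged_profile_returned(self, corpus, registry):
        fm = ak.compute_fingerprints(corpus[:5], "maccs")
        ds = ak.LabeledDataset(fm, np.array([0, 1, 0, 1, 0.0]), task="classification")
        wrong = train(ds, ModelConfig("decision_tree", "classification", seed=0))
        rows = systematic_profile(corpus[0], {**registry, "broken": wrong})
        broken = [r for r in rows if r.endpoint == "broken"][0]
        assert broken.failed
        assert len(rows) == 4

    def test_empty_registry_errors(self, corpus):
        with pytest.raises(ValueError):
            systematic_profile(corpus[0], {})


def test_store_computes_missing_columns(tmp_path):
    df = pd.DataFrame({"id": ["a"], "smiles": ["CCO"]})
    p = tmp_path / "s.csv"
    df.to_csv(p, index=False)
    store = AdmetRecordStore.from_csv(p)
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    assert store.table["MW"][0] == pytest.approx(Descriptors.MolWt(Chem.MolFromSmiles("CCO")))
    assert store.table["HBD"][0] == 1
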