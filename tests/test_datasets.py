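"""Dataset construction: dedup, weak-binder negatives, allocation, encoding."""

import numpy as np
import pytest

from dtiscreen.datasets import (
    PAIR_WIDTH,
    InteractionRecord,
    SplitSpec,
    allocate_negatives,
    dedup_interactions,
    encode_dataset,
    filter_weak_binders,
    fingerprint_redundancy_report,
    nm_to_um,
    read_interactions,
    write_interactions,
)
from dtiscreen.drug_descriptors import parse_ligand
from dtiscreen.synthetic_fixtures import fixture_ligands, random_protein


def rec(d, t, label="positive", source="A", bio=None):
    return InteractionRecord(d, t, label, source, bio)


class TestDedup:
    def test_duplicate_keeps_earliest_source(self):
        out = dedup_interactions(
            [rec("d1", "t1", source="A"), rec("d1", "t1", source="B")],
            set_order=("A", "B"),
        )
        assert len(out) == 1
        assert out[0].source == "A"

    def test_label_conflict_keeps_positive(self, caplog):
        out = dedup_interactions(
            [rec("d1", "t1", "positive", "A"), rec("d1", "t1", "negative", "B")]
        )
        assert len(out) == 1
        assert out[0].label == "positive"
        out2 = dedup_interactions(
            [rec("d1", "t1", "negative", "A"), rec("d1", "t1", "positive", "B")]
        )
        assert out2[0].label == "positive"

    def test_planted_duplicates_removed(self):
        rng = np.random.default_rng(0)
        base = [rec(f"d{i}", f"t{i}") for i in range(80)]
        dupes = [rec(f"d{i}", f"t{i}", source="B") for i in rng.choice(80, 20, replace=False)]
        out = dedup_interactions(base + dupes)
        assert len(out) == 80

    def test_idempotent(self):
        records = [rec("d1", "t1"), rec("d2", "t2"), rec("d1", "t1", source="B")]
        once = dedup_interactions(records)
        assert dedup_interactions(once) == once


class TestFilterWeakBinders:
    def test_strictly_greater_than_threshold(self):
        records = [rec("d", f"t{i}", "unknown", bio=b)
                   for i, b in enumerate([0.1, 10.0, 10.1, 500.0])]
        out = filter_weak_binders(records)
        assert len(out) == 2
        assert all(r.label == "negative" for r in out)
        assert all(r.bioactivity > 10.0 for r in out)

    def test_all_strong_binders_yield_empty(self):
        records = [rec("d", f"t{i}", "unknown", bio=b) for i, b in enumerate([0.5, 10.0])]
        assert filter_weak_binders(records) == []

    def test_missing_bioactivity_skipped(self):
        out = filter_weak_binders([rec("d", "t", "unknown", bio=None)])
        assert out == []

    def test_nanomolar_conversion(self):
        # 15,000 nM = 15 uM -> weak binder; 5,000 nM = 5 uM -> not
        records = [
            rec("d", "t1", "unknown", bio=nm_to_um(15_000.0)),
            rec("d", "t2", "unknown", bio=nm_to_um(5_000.0)),
        ]
        out = filter_weak_binders(records)
        assert [r.target_id for r in out] == ["t1"]
        assert out[0].bioactivity == pytest.approx(15.0)


class TestRedundancyReport:
    def test_identical_ligands_fraction_one(self):
        ligs = [parse_ligand("a", "CCO"), parse_ligand("b", "CCO")]
        frac, pairs = fingerprint_redundancy_report(ligs)
        assert (frac, pairs) == (1.0, 1)

    def test_dissimilar_ligands_fraction_zero(self):
        ligs = [parse_ligand("a", "CCO"), parse_ligand("b", "c1ccccc1N")]
        frac, pairs = fingerprint_redundancy_report(ligs)
        assert frac == 0.0 and pairs == 1

    def test_pair_count_and_single_ligand(self):
        ligs = [parse_ligand(i, s) for i, s in fixture_ligands()[:6]]
        _, pairs = fingerprint_redundancy_report(ligs)
        assert pairs == 15
        assert fingerprint_redundancy_report(ligs[:1]) == (0.0, 0)

    def test_hand_tanimoto(self):
        # 2 shared bits of 4 in the union -> 0.5, independent of any toolkit
        a, b = {1, 2, 3}, {2, 3, 4}
        assert len(a & b) / len(a | b) == 0.5


class TestAllocateNegatives:
    def make_pool(self, n, tag="n"):
        return [rec(f"{tag}d{i}", f"{tag}t{i}", "negative", "pool") for i in range(n)]

    def test_quota_arithmetic(self):
        positives = [[rec(f"pd{i}", f"pt{i}") for i in range(4)],
                     [rec(f"qd{i}", f"qt{i}") for i in range(2)]]
        out = allocate_negatives(positives, self.make_pool(9), SplitSpec(1.5, seed=0))
        assert [len(x) for x in out] == [6, 3]

    def test_empty_pool(self):
        positives = [[rec("a", "b")], [rec("c", "d")]]
        out = allocate_negatives(positives, [], SplitSpec(1.5, seed=0))
        assert [len(x) for x in out] == [0, 0]

    def test_conservation_and_disjointness_fuzz(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            sizes = rng.integers(1, 20, size=int(rng.integers(1, 4)))
            positives = [
                [rec(f"p{s}d{i}", f"p{s}t{i}") for i in range(int(sz))]
                for s, sz in enumerate(sizes)
            ]
            pool = self.make_pool(int(rng.integers(0, 60)))
            out = allocate_negatives(
                positives, pool, SplitSpec(1.5, seed=int(rng.integers(1000)))
            )
            keys = [r.key for chunk in out for r in chunk]
            assert len(keys) == len(pool)               # union = pool
            assert len(set(keys)) == len(keys)          # pairwise disjoint

    def test_seed_determinism_and_variation(self):
        positives = [[rec(f"pd{i}", f"pt{i}") for i in range(10)]]
        pool = self.make_pool(30)
        a = allocate_negatives(positives, pool, SplitSpec(1.5, seed=5))
        b = allocate_negatives(positives, pool, SplitSpec(1.5, seed=5))
        c = allocate_negatives(positives, pool, SplitSpec(1.5, seed=6))
        assert a == b
        assert [len(x) for x in a] == [len(x) for x in c]
        assert a != c

    def test_overlap_with_positives_rejected(self):
        positives = [[rec("d0", "t0")]]
        pool = [rec("d0", "t0", "negative", "pool")]
        with pytest.raises(ValueError, match="overlaps"):
            allocate_negatives(positives, pool, SplitSpec(1.5, seed=0))

    def test_published_split_sizes_via_override(self):
        # the two positive sets and the negative pool of the published
        # corpus construction, at identity granularity only
        positives = [
            [rec(f"yd{i}", f"yt{i}") for i in range(7206)],
            [rec(f"bd{i}", f"bt{i}") for i in range(3530)],
        ]
        pool = self.make_pool(16209)
        out = allocate_negatives(
            positives, pool, SplitSpec(1.5, seed=1), override=[10912, 5297]
        )
        training = len(positives[0]) + len(out[0])
        external = len(positives[1]) + len(out[1])
        assert training == 18118
        assert external == 8827


class TestEncodeDataset:
    def test_entity_caching(self, monkeypatch):
        import dtiscreen.datasets as ds_mod

        calls = {"protein": 0, "drug": 0}
        real_pf, real_df = ds_mod.protein_features, ds_mod.drug_features

        def counting_pf(seq):
            calls["protein"] += 1
            return real_pf(seq)

        def counting_df(smiles, id=""):
            calls["drug"] += 1
            return real_df(smiles, id)

        monkeypatch.setattr(ds_mod, "protein_features", counting_pf)
        monkeypatch.setattr(ds_mod, "drug_features", counting_df)

        seqs = {f"t{i}": random_protein(50, seed=i, id=f"t{i}") for i in (1, 2)}
        ligs = {"d1": "CCO", "d2": "CC(=O)O"}
        records = [rec("d1", "t1"), rec("d1", "t2"), rec("d2", "t1")]
        out = ds_mod.encode_dataset(records, seqs, ligs)
        assert out.features.shape == (3, PAIR_WIDTH)
        assert calls == {"protein": 2, "drug": 2}

    def test_empty_records(self):
        out = encode_dataset([], {}, {})
        assert out.features.shape == (0, PAIR_WIDTH)

    def test_missing_entities_dropped(self):
        seqs = {"t1": random_protein(50, seed=0, id="t1")}
        ligs = {"d1": "CCO"}
        records = [rec("d1", "t1"), rec("d1", "tX"), rec("dX", "t1")]
        out = encode_dataset(records, seqs, ligs)
        assert [r.key for r in out.records] == [("d1", "t1")]

    def test_row_width(self):
        seqs = {"t1": random_protein(60, seed=1, id="t1")}
        out = encode_dataset([rec("d1", "t1")], seqs, {"d1": "CCO"})
        assert out.features.shape[1] == PAIR_WIDTH
        assert len(out.feature_names) == PAIR_WIDTH


def test_interactions_round_trip(tmp_path):
    records = [
        rec("d1", "t1", "positive", "A", 0.5),
        rec("d2", "t2", "negative", "B", 120.0),
        InteractionRecord("d3", "t3", "unknown", "C", None, None),
    ]
    path = tmp_path / "interactions.tsv"
    write_interactions(records, path)
    assert read_interactions(path) == records


def test_record_validation():
    with pytest.raises(ValueError, match="label"):
        InteractionRecord("d", "t", "maybe")
    with pytest.raises(ValueError, match="bioactivity"):
        InteractionRecord("d", "t", "positive", bioactivity=-1.0)
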