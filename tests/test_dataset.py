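"""Neutral sampling, gene-disjoint splitting, homology clustering."""

import numpy as np
import pandas as pd
import pytest

from varmode import dataset
from varmode.dataset import (
    HomologyClustering,
    alignment_identity,
    cluster_homologs,
    enforce_homology_split,
    sample_neutral,
    split,
    SplitResult,
)
from varmode.simulate import SyntheticSpec, gen_variant_dataset


class TestSampleNeutral:
    def test_min_of_class_counts(self, rng):
        pool = {"G1": list(range(20))}
        out = sample_neutral({"G1": (10, 4)}, pool, rng)
        assert len(out["G1"]) == 4

    def test_floor_of_two(self, rng):
        out = sample_neutral({"G1": (0, 1)}, {"G1": list(range(20))}, rng)
        assert len(out["G1"]) == 2

    def test_capped_by_pool(self, rng):
        out = sample_neutral({"G1": (5, 5)}, {"G1": [1, 2, 3]}, rng)
        assert len(out["G1"]) == 3

    def test_empty_pool_skipped_with_warning(self, rng):
        with pytest.warns(UserWarning, match="no neutral candidates"):
            out = sample_neutral({"G1": (3, 3)}, {"G1": []}, rng)
        assert "G1" not in out

    def test_sampling_without_replacement(self, rng):
        out = sample_neutral({"G1": (8, 8)}, {"G1": list(range(10))}, rng)
        assert len(out["G1"]) == len(set(out["G1"])) == 8


class TestSplit:
    @pytest.fixture(scope="class")
    def split_300(self):
        spec = SyntheticSpec(seed=1, n_genes=300, variants_per_gene=10)
        variants, _, _ = gen_variant_dataset(spec)
        return variants, split(variants, 0.9, np.random.default_rng(0))

    def test_train_share_near_target(self, split_300):
        variants, result = split_300
        share = len(result.train) / len(variants)
        assert 0.88 <= share <= 0.92

    def test_gene_disjointness(self, split_300):
        _, result = split_300
        assert not (set(result.train["gene"]) & set(result.test["gene"]))

    def test_per_class_stratification(self, split_300):
        variants, result = split_300
        for cls in ("GOF", "LOF", "NEUTRAL"):
            total = (variants["label"] == cls).sum()
            in_train = (result.train["label"] == cls).sum()
            assert abs(in_train / total - 0.9) <= 0.03

    def test_single_gene_degenerate(self):
        variants = pd.DataFrame(
            {"gene": ["G1"] * 5, "label": ["GOF", "LOF", "LOF", "NEUTRAL", "NEUTRAL"]}
        )
        result = split(variants, 0.9, np.random.default_rng(0))
        assert len(result.train) + len(result.test) == 5
        assert len(result.train) == 0 or len(result.test) == 0

    def test_invalid_fraction(self):
        variants = pd.DataFrame({"gene": ["a", "b"], "label": ["GOF", "LOF"]})
        with pytest.raises(ValueError):
            split(variants, 1.5, np.random.default_rng(0))


class TestClusterHomologs:
    def test_identical_sequences_one_cluster(self):
        seq = "MKTLLVLAVCLAAGSQA" * 5
        clustering = cluster_homologs({"A": seq, "B": seq})
        assert clustering.assignment["A"] == clustering.assignment["B"]

    def test_random_sequences_separate_clusters(self):
        # Two random length-200 sequences: expected global identity is far
        # below 40% (oracle: the exact alignment identity itself).
        rng = np.random.default_rng(42)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        s1 = "".join(rng.choice(aas, 200))
        s2 = "".join(rng.choice(aas, 200))
        assert alignment_identity(s1, s2) < 0.4
        clustering = cluster_homologs({"A": s1, "B": s2})
        assert clustering.assignment["A"] != clustering.assignment["B"]

    def test_threshold_one_every_distinct_alone(self):
        seqs = {"A": "MKTAYIAK", "B": "MKTAYIAQ", "C": "MKTAYIAK"}
        clustering = cluster_homologs(seqs, identity_threshold=1.0)
        assert clustering.assignment["A"] == clustering.assignment["C"]
        assert clustering.assignment["A"] != clustering.assignment["B"]

    def test_every_protein_clustered_once(self):
        rng = np.random.default_rng(1)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = {f"P{i}": "".join(rng.choice(aas, 60)) for i in range(8)}
        clustering = cluster_homologs(seqs)
        assert set(clustering.assignment) == set(seqs)
        members = [p for mem in clustering.members.values() for p in mem]
        assert sorted(members) == sorted(seqs)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_homologs({})

    def test_identity_oracle_known_case(self):
        # 9 of 10 positions identical, no gaps needed.
        assert alignment_identity("MKTAYIAKQR", "MKTAYIAKQW") == pytest.approx(0.9)


def _mini_split(train_rows, test_rows):
    cols = ["variant_id", "gene", "protein", "label"]
    train = pd.DataFrame(train_rows, columns=cols)
    test = pd.DataFrame(test_rows, columns=cols)
    return SplitResult(train, test, {})


class TestEnforceHomologySplit:
    def test_minor_member_dropped(self):
        sp = _mini_split(
            [(f"v{i}", "G1", "A", "LOF") for i in range(5)]
            + [(f"w{i}", "G2", "B", "LOF") for i in range(2)],
            [],
        )
        clustering = HomologyClustering(
            assignment={"A": 0, "B": 0}, members={0: ["A", "B"]},
            representative={0: "A"},
        )
        out = enforce_homology_split(sp, clustering)
        assert set(out.train["protein"]) == {"A"}
        assert len(out.train) == 5

    def test_disjoint_clusters_unchanged(self):
        sp = _mini_split(
            [("v1", "G1", "A", "GOF")], [("v2", "G2", "B", "LOF")]
        )
        clustering = HomologyClustering(
            assignment={"A": 0, "B": 1}, members={0: ["A"], 1: ["B"]},
            representative={0: "A", 1: "B"},
        )
        out = enforce_homology_split(sp, clustering)
        assert len(out.train) == 1 and len(out.test) == 1

    def test_cluster_straddling_partitions_purged_from_test(self):
        # Representative (most variants) in train; homolog in test dropped.
        sp = _mini_split(
            [(f"v{i}", "G1", "A", "LOF") for i in range(4)],
            [("w0", "G2", "B", "LOF")],
        )
        clustering = HomologyClustering(
            assignment={"A": 0, "B": 0}, members={0: ["A", "B"]},
            representative={0: "A"},
        )
        out = enforce_homology_split(sp, clustering)
        assert len(out.train) == 4 and len(out.test) == 0

    def test_all_proteins_one_cluster_single_survivor(self):
        sp = _mini_split(
            [("v0", "G1", "A", "LOF"), ("v1", "G2", "B", "LOF"),
             ("v2", "G2", "B", "GOF"), ("v3", "G3", "C", "LOF")],
            [],
        )
        clustering = HomologyClustering(
            assignment={"A": 0, "B": 0, "C": 0}, members={0: ["A", "B", "C"]},
            representative={0: "A"},
        )
        out = enforce_homology_split(sp, clustering)
        assert set(out.train["protein"]) == {"B"}  # most labeled variants


class TestVariantIO:
    def test_tsv_roundtrip(self, tmp_path):
        variants, _, _ = gen_variant_dataset(
            SyntheticSpec(seed=2, n_genes=5, variants_per_gene=3)
        )
        path = tmp_path / "v.tsv"
        dataset.write_variants_tsv(variants, path)
        back = dataset.read_variants_tsv(path)
        pd.testing.assert_frame_equal(variants.reset_index(drop=True), back)

    def test_vcf_roundtrip(self, tmp_path):
        variants, _, _ = gen_variant_dataset(
            SyntheticSpec(seed=3, n_genes=4, variants_per_gene=2)
        )
        variants = variants.sort_values(["chrom", "pos"]).reset_index(drop=True)
        path = tmp_path / "v.vcf"
        dataset.write_variants_vcf(variants, path)
        back = dataset.read_variants_vcf(path)
        assert list(back["variant_id"]) == list(variants["variant_id"])
        assert list(back["gene"]) == list(variants["gene"])
        assert list(back["pos"]) == list(variants["pos"])
        assert list(back["label"]) == list(variants["label"])
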