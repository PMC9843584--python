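"""Dataset I/O, edit-distance splitting, truncation, imbalance, replicates."""

from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

from ntaug import codon_model as cm
from ntaug import data_pipeline as dp
from ntaug.augmentation import AugmentationConfig
from ntaug.dataset import LabeledDataset, LabeledRecord
from ntaug.errors import (
    AmbiguousMinorityError,
    DegenerateSplitError,
    InfeasibleRatioError,
    ParseError,
)

from conftest import make_classification_dataset, make_regression_dataset


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        data = make_regression_dataset(["ACDE", "MSKL", "WWWW"], labels=[0.5, 1.5, -2.0])
        path = tmp_path / "d.csv"
        dp.write_dataset(data, path)
        back = dp.read_dataset(path, alphabet="amino_acid", task="regression")
        assert [(r.id, r.sequence, r.label) for r in back] == [
            (r.id, r.sequence, r.label) for r in data
        ]

    def test_lowercase_sequences_uppercased(self, tmp_path):
        path = tmp_path / "d.csv"
        pd.DataFrame({"sequence": ["acde"], "label": [1.0]}).to_csv(path, index=False)
        back = dp.read_dataset(path, alphabet="amino_acid", task="regression")
        assert back[0].sequence == "ACDE"

    def test_non_numeric_label_rejected(self, tmp_path):
        path = tmp_path / "d.csv"
        pd.DataFrame({"sequence": ["ACDE", "MSKL"], "label": [1.0, "x"]}).to_csv(path, index=False)
        with pytest.raises(ParseError, match="row 2"):
            dp.read_dataset(path, alphabet="amino_acid", task="regression")

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "d.csv"
        pd.DataFrame({"seq": ["ACDE"]}).to_csv(path, index=False)
        with pytest.raises(ParseError, match="missing"):
            dp.read_dataset(path, alphabet="amino_acid", task="regression")

    def test_fasta_with_sidecar_labels(self, tmp_path):
        fasta = tmp_path / "s.fasta"
        fasta.write_text(">a\nACDE\n>b\nMSKL\n")
        labels = tmp_path / "l.csv"
        pd.DataFrame({"id": ["a", "b"], "label": [0.1, 0.2]}).to_csv(labels, index=False)
        data = dp.read_dataset(fasta, alphabet="amino_acid", task="regression",
                               format="fasta+csv", labels_path=labels)
        assert [(r.id, r.sequence, r.label) for r in data] == [
            ("a", "ACDE", 0.1), ("b", "MSKL", 0.2)
        ]


@lru_cache(maxsize=None)
def _lev_oracle(a: str, b: str) -> int:
    """Plain recursive Levenshtein, independent of the implementation."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(
        _lev_oracle(a[1:], b) + 1,
        _lev_oracle(a, b[1:]) + 1,
        _lev_oracle(a[1:], b[1:]) + (a[0] != b[0]),
    )


class TestEditDistance:
    @pytest.mark.parametrize(
        "a,b,d",
        [("ACDE", "ACDE", 0), ("ACDE", "ACDF", 1), ("ACDE", "ACDDE", 1), ("", "AC", 2)],
    )
    def test_examples(self, a, b, d):
        assert dp.edit_distance(a, b) == d

    def test_against_recursive_oracle(self, rng):
        aas = list("ACDEF")
        for _ in range(50):
            a = "".join(rng.choice(aas, size=int(rng.integers(0, 7))))
            b = "".join(rng.choice(aas, size=int(rng.integers(0, 7))))
            assert dp.edit_distance(a, b) == _lev_oracle(a, b)
            assert dp.edit_distance(a, b) == dp.edit_distance(b, a)


class TestSplit:
    def make_data(self):
        wt = "AAAA"
        seqs = ["AAAC", "AACC", "ACCC", "CCCC", "CCCD", "AAAD", "AADD", "DDDD",
                "AAAE", "AAEE", "DDDC", "EEEE", "AAAG", "AGGC", "GGGG", "AAGG"]
        return wt, make_regression_dataset(seqs, labels=list(np.linspace(0, 1, len(seqs))))

    def test_partition_by_threshold(self):
        wt, data = self.make_data()
        out = dp.split_by_edit_distance(data, dp.SplitSpec(wt, 2), seed=0)
        for r in out:
            ed = dp.edit_distance(r.sequence, wt)
            if ed <= 2:
                assert r.split in ("train", "valid")
            else:
                assert r.split == "test"

    def test_no_leakage_and_exhaustive(self):
        wt, data = self.make_data()
        out = dp.split_by_edit_distance(data, dp.SplitSpec(wt, 2), seed=0)
        tags = [r.split for r in out]
        assert all(t in ("train", "valid", "test") for t in tags)
        near = {r.sequence for r in out if r.split in ("train", "valid")}
        far = {r.sequence for r in out if r.split == "test"}
        assert not near & far

    def test_valid_fraction_count(self):
        wt, data = self.make_data()
        out = dp.split_by_edit_distance(data, dp.SplitSpec(wt, 2, valid_fraction=0.25), seed=0)
        n_near = sum(1 for r in out if r.split in ("train", "valid"))
        n_valid = sum(1 for r in out if r.split == "valid")
        assert n_valid == round(0.25 * n_near)

    def test_degenerate_split_raises(self):
        data = make_regression_dataset(["AAAC", "AAAD"])
        with pytest.raises(DegenerateSplitError):
            dp.split_by_edit_distance(data, dp.SplitSpec("AAAA", 7), seed=0)


class TestStratifiedTruncate:
    def test_identity_at_fraction_one(self):
        data = make_regression_dataset(["AC", "CD", "DE"], labels=[1.0, 2.0, 3.0])
        assert dp.stratified_truncate(data, 1.0) is data

    def test_two_equal_bins(self):
        # 100 records in two well-separated label groups: 10% keeps 5 + 5
        seqs = [f"{'A' * 5}" for _ in range(100)]
        data = LabeledDataset(
            [
                LabeledRecord(f"r{i}", "AAAAA", 0.0 + 0.001 * i if i < 50 else 10.0 + 0.001 * i)
                for i in range(100)
            ],
            alphabet="amino_acid",
            task="regression",
        )
        out = dp.stratified_truncate(data, 0.1, n_bins=2, seed=0)
        assert len(out) == 10
        labels = out.labels
        assert (labels < 5).sum() == 5 and (labels > 5).sum() == 5

    def test_determinism(self):
        data = make_regression_dataset(
            ["AAAA"] * 0 + [f"AC" for _ in range(30)], labels=list(np.arange(30.0))
        )
        a = dp.stratified_truncate(data, 0.3, seed=4)
        b = dp.stratified_truncate(data, 0.3, seed=4)
        assert [r.id for r in a] == [r.id for r in b]

    def test_size_monotone_in_fraction(self):
        data = make_regression_dataset(["AC"] * 40, labels=list(np.arange(40.0)))
        sizes = [len(dp.stratified_truncate(data, f, seed=1)) for f in (0.1, 0.25, 0.5, 0.9)]
        assert sizes == sorted(sizes)
        assert sizes == [int(np.ceil(f * 40)) for f in (0.1, 0.25, 0.5, 0.9)]


class TestImbalance:
    def test_downsample_arithmetic(self):
        data = make_classification_dataset(["AC"] * 1000, [1] * 500 + [0] * 500)
        out = dp.impose_class_imbalance(data, 0.1, seed=0)
        labels = out.labels
        assert labels.sum() == 50 and (1 - labels).sum() == 500

    def test_ratio_one_identity_on_balanced(self):
        data = make_classification_dataset(["AC"] * 10, [1] * 5 + [0] * 5)
        out = dp.impose_class_imbalance(data, 1.0, seed=0)
        assert [r.id for r in out] == [r.id for r in data]

    def test_infeasible_ratio(self):
        data = make_classification_dataset(["AC"] * 550, [1] * 50 + [0] * 500)
        with pytest.raises(InfeasibleRatioError):
            dp.impose_class_imbalance(data, 0.2, seed=0)

    @pytest.mark.parametrize("ratio", [0.1, 0.3, 0.5, 0.7, 1.0])
    def test_exact_counts_across_ratios(self, ratio):
        data = make_classification_dataset(["AC"] * 400, [1] * 200 + [0] * 200)
        out = dp.impose_class_imbalance(data, ratio, seed=1)
        assert out.labels.sum() == round(ratio * 200)


class TestMinorityAugmentation:
    def test_counts(self, natural):
        data = make_classification_dataset(
            ["MS"] * 10 + ["KL"] * 100, [1] * 10 + [0] * 100
        )
        cfg = AugmentationConfig(5, "random", natural, seed=0)
        out = dp.augment_minority_class(data, cfg)
        labels = out.labels
        assert labels.sum() == 50           # minority x n_aug
        assert (1 - labels).sum() == 100    # majority reverse translated once
        assert out.alphabet == "nucleotide"

    def test_n_aug_one_is_pure_reverse_translation(self, natural):
        data = make_classification_dataset(["MS"] * 3 + ["KL"] * 7, [1] * 3 + [0] * 7)
        out = dp.augment_minority_class(data, AugmentationConfig(1, "random", natural, seed=0))
        assert len(out) == 10

    def test_balanced_input_requires_explicit_minority(self, natural):
        data = make_classification_dataset(["MS"] * 5 + ["KL"] * 5, [1] * 5 + [0] * 5)
        cfg = AugmentationConfig(2, "random", natural, seed=0)
        with pytest.raises(AmbiguousMinorityError):
            dp.augment_minority_class(data, cfg)
        out = dp.augment_minority_class(data, cfg, minority_label=1.0)
        assert out.labels.sum() == 10


class TestReplicates:
    def test_deterministic_mode_identical(self, natural):
        data = make_regression_dataset(["MSKL", "WWCD"])
        reps = dp.make_test_replicates(data, natural, "deterministic", 0, 5)
        seqs = [tuple(r.sequence for r in rep) for rep in reps.replicates]
        assert len(set(seqs)) == 1

    def test_random_mode_same_translation_different_nt(self, natural):
        data = make_regression_dataset(["MSKLSSRR", "WWCDLLEE"])
        reps = dp.make_test_replicates(data, natural, "random", 0, 5)
        for rep in reps.replicates:
            assert [cm.translate(r.sequence, natural) for r in rep] == data.sequences
        all_nt = [tuple(r.sequence for r in rep) for rep in reps.replicates]
        assert len(set(all_nt)) > 1

    def test_empty_test_set(self, natural):
        data = make_regression_dataset([])
        reps = dp.make_test_replicates(data, natural, "random", 0, 5)
        assert len(reps.replicates) == 5
        assert all(len(rep) == 0 for rep in reps.replicates)
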