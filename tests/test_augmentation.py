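"""Offline and online augmentation semantics."""

import warnings

import numpy as np
import pytest

from ntaug import augmentation as aug
from ntaug import codon_model as cm
from ntaug.dataset import LabeledDataset, LabeledRecord
from ntaug.errors import AugmentationWarning, ConfigError

from conftest import make_regression_dataset


def rec(seq, label=1.0, rid="r0"):
    return LabeledRecord(id=rid, sequence=seq, label=label)


class TestOfflineIterative:
    def test_capacity_one_caps_output(self, natural):
        cfg = aug.AugmentationConfig(5, "iterative", natural)
        with pytest.warns(AugmentationWarning):
            out = aug.augment_offline_iterative(rec("M"), cfg)
        assert [r.sequence for r in out] == ["ATG"]

    def test_full_enumeration_matches_brute_force(self, natural):
        cfg = aug.AugmentationConfig(6, "iterative", natural)
        out = aug.augment_offline_iterative(rec("MS"), cfg)
        assert len(out) == 6
        assert len({r.sequence for r in out}) == 6
        assert {cm.translate(r.sequence, natural) for r in out} == {"MS"}
        assert {r.sequence for r in out} == set(cm.enumerate_synonyms("MS", natural))

    def test_leftmost_position_varies_fastest(self, natural):
        cfg = aug.AugmentationConfig(3, "iterative", natural)
        out = aug.augment_offline_iterative(rec("KK"), cfg)
        assert [r.sequence for r in out] == ["AAAAAA", "AAGAAA", "AAAAAG"]

    def test_first_output_is_deterministic_reverse_translation(self, natural):
        cfg = aug.AugmentationConfig(4, "iterative", natural)
        out = aug.augment_offline_iterative(rec("LSW"), cfg)
        assert out[0].sequence == cm.reverse_translate("LSW", natural)

    def test_provenance_and_labels(self, natural):
        cfg = aug.AugmentationConfig(3, "iterative", natural)
        out = aug.augment_offline_iterative(rec("SS", label=2.5, rid="x1"), cfg)
        assert [r.aug_index for r in out] == [0, 1, 2]
        assert all(r.parent_id == "x1" and r.label == 2.5 for r in out)


class TestOfflineRandom:
    def test_capacity_one_duplicates_with_warning(self, natural):
        cfg = aug.AugmentationConfig(4, "random", natural, seed=0)
        with pytest.warns(AugmentationWarning):
            out = aug.augment_offline_random(rec("M"), cfg)
        assert [r.sequence for r in out] == ["ATG"] * 4

    def test_samples_within_enumerable_synonyms(self, natural):
        cfg = aug.AugmentationConfig(100, "random", natural, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", AugmentationWarning)
            out = aug.augment_offline_random(rec("MS"), cfg)
        assert len(out) == 100
        assert {r.sequence for r in out} <= set(cm.enumerate_synonyms("MS", natural))

    def test_seed_determinism(self, natural):
        cfg = aug.AugmentationConfig(3, "random", natural, seed=11)
        a = [r.sequence for r in aug.augment_offline_random(rec("LSW"), cfg)]
        b = [r.sequence for r in aug.augment_offline_random(rec("LSW"), cfg)]
        assert a == b


class TestOfflineDataset:
    def test_counts_multiply(self, natural):
        data = make_regression_dataset(["LS", "SW"])
        cfg = aug.AugmentationConfig(5, "random", natural, seed=0)
        out = aug.augment_dataset_offline(data, cfg)
        assert len(out) == 10
        assert out.alphabet == "nucleotide"

    def test_empty_dataset(self, natural):
        data = make_regression_dataset([])
        out = aug.augment_dataset_offline(data, aug.AugmentationConfig(5, "random", natural))
        assert len(out) == 0

    def test_iterative_capacity_cap_with_warning(self, natural):
        data = make_regression_dataset(["MS"])
        cfg = aug.AugmentationConfig(10, "iterative", natural)
        with pytest.warns(AugmentationWarning):
            out = aug.augment_dataset_offline(data, cfg)
        assert len(out) == 6

    def test_order_stable_and_labels_preserved(self, natural):
        data = make_regression_dataset(["KK", "MS"], labels=[0.1, 0.9])
        out = aug.augment_dataset_offline(
            data, aug.AugmentationConfig(2, "iterative", natural)
        )
        assert [(r.parent_id, r.aug_index) for r in out] == [
            ("r0", 0), ("r0", 1), ("r1", 0), ("r1", 1)
        ]
        assert [r.label for r in out] == [0.1, 0.1, 0.9, 0.9]

    def test_rejects_nucleotide_dataset(self, natural):
        data = LabeledDataset(
            [LabeledRecord("n0", "ATG", 1.0)], alphabet="nucleotide", task="regression"
        )
        with pytest.raises(ConfigError):
            aug.augment_dataset_offline(data, aug.AugmentationConfig(2, "random", natural))


class TestOnline:
    def test_threshold_one_is_identity(self, natural, rng):
        cfg = aug.OnlineAugmentConfig(t_aug=1.0, num_subs=0.25, table=natural)
        batch = ["ATGAGCAAA", "TGGATGAAA"]
        assert aug.augment_online_batch(batch, cfg, rng) == batch

    def test_no_degenerate_positions_passes_through(self, natural, rng):
        cfg = aug.OnlineAugmentConfig(t_aug=0.0, num_subs=1.0, table=natural)
        batch = ["ATGATGATG"] * 5  # all-Met: no synonymous alternative exists
        assert aug.augment_online_batch(batch, cfg, rng) == batch

    def test_modification_rate_and_hamming_bound(self, natural):
        """With t_aug=0.5, about half the batch is modified, and each modified
        9-codon sequence differs in at most floor(0.25 * 9) = 2 codons."""
        cfg = aug.OnlineAugmentConfig(t_aug=0.5, num_subs=0.25, table=natural)
        base = cm.reverse_translate("LSWKSPRDE", natural)
        batch = [base] * 1000
        out = aug.augment_online_batch(batch, cfg, np.random.default_rng(5))
        n_modified = 0
        for s in out:
            diff = sum(
                s[i : i + 3] != base[i : i + 3] for i in range(0, len(base), 3)
            )
            if diff:
                n_modified += 1
                assert 1 <= diff <= 2
            assert cm.translate(s, natural) == "LSWKSPRDE"
        assert 440 <= n_modified <= 560  # ~Binomial(1000, 0.5), +/- ~3.5 sd

    @pytest.mark.parametrize("table_name", ["natural", "balanced", "shuffled"])
    def test_synonymy_property_all_tables(self, table_name, all_tables, aa_random_sequences):
        table = all_tables[table_name]
        cfg = aug.OnlineAugmentConfig(t_aug=0.0, num_subs=0.5, table=table)
        rng = np.random.default_rng(9)
        batch = [cm.reverse_translate(aa, table, "random", rng) for aa in aa_random_sequences]
        out = aug.augment_online_batch(batch, cfg, rng)
        assert len(out) == len(batch)
        for aa, nt in zip(aa_random_sequences, out):
            assert cm.translate(nt, table) == aa

    def test_rng_determinism(self, natural):
        cfg = aug.OnlineAugmentConfig(t_aug=0.3, num_subs=0.5, table=natural)
        batch = [cm.reverse_translate("LSWKSP", natural)] * 20
        a = aug.augment_online_batch(batch, cfg, np.random.default_rng(2))
        b = aug.augment_online_batch(batch, cfg, np.random.default_rng(2))
        assert a == b


class TestConfigValidation:
    def test_n_aug_must_be_positive(self, natural):
        with pytest.raises(ConfigError):
            aug.AugmentationConfig(0, "random", natural)

    def test_online_bounds(self, natural):
        with pytest.raises(ConfigError):
            aug.OnlineAugmentConfig(t_aug=1.5, table=natural)
        with pytest.raises(ConfigError):
            aug.OnlineAugmentConfig(num_subs=0.0, table=natural)


@pytest.mark.parametrize("table_name", ["natural", "balanced", "shuffled"])
@pytest.mark.parametrize("method", ["iterative", "random"])
def test_offline_synonymy_property(table_name, method, all_tables, aa_random_sequences):
    """Every offline-augmented sequence translates back to its parent, for
    both sampling methods and all three codon-table types."""
    table = all_tables[table_name]
    cfg = aug.AugmentationConfig(4, method, table, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", AugmentationWarning)
        for aa in aa_random_sequences[:15]:
            if method == "iterative":
                out = aug.augment_offline_iterative(rec(aa), cfg)
            else:
                out = aug.augment_offline_random(rec(aa), cfg)
            assert all(cm.translate(r.sequence, table) == aa for r in out)
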