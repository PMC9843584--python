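"""Dataset I/O and data-handling protocols.

This module implements the data protocols around augmentation: reading and
writing labeled sequence CSV/FASTA files, Levenshtein edit distance,
edit-distance train/validation/test splitting (train on variants close to
wild type, test on distant ones, to measure extrapolation), stratified
training-set truncation, synthetic class imbalance, minority-class-only
augmentation, and generation of five reverse-translated test-set replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from sklearn.model_selection import train_test_split

from . import codon_model
from .augmentation import AugmentationConfig, augment_dataset_offline
from .codon_model import CodonTable
from .dataset import LabeledDataset, LabeledRecord
from .errors import (
    AmbiguousMinorityError,
    ConfigError,
    DegenerateSplitError,
    InfeasibleRatioError,
    NtaugWarning,
    ParseError,
)

__all__ = [
    "SplitSpec",
    "TestReplicateSet",
    "read_dataset",
    "write_dataset",
    "edit_distance",
    "split_by_edit_distance",
    "stratified_truncate",
    "impose_class_imbalance",
    "augment_minority_class",
    "make_test_replicates",
]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_dataset(
    path: str | Path,
    alphabet: str,
    task: str,
    format: str = "csv",
    labels_path: str | Path | None = None,
) -> LabeledDataset:
    """Read a labeled dataset from ``csv`` or ``fasta+csv``.

    CSV needs header columns ``sequence,label`` (optional ``id``, ``set``,
    ``parent_id``, ``aug_index``). For ``fasta+csv`` the FASTA holds the
    sequences and ``labels_path`` a CSV with columns ``id,label[,set]`` keyed
    by FASTA record id.
    """
    path = Path(path)
    if format == "csv":
        try:
            frame = pd.read_csv(path, dtype={"sequence": str})
        except Exception as exc:  # pandas raises many flavours
            raise ParseError(f"{path}: {exc}") from exc
        return LabeledDataset.from_frame(frame, alphabet=alphabet, task=task)
    if format == "fasta+csv":
        if labels_path is None:
            raise ParseError("fasta+csv format requires labels_path")
        labels = pd.read_csv(labels_path)
        if "id" not in labels.columns or "label" not in labels.columns:
            raise ParseError(f"{labels_path}: label CSV needs columns id,label")
        table = labels.set_index(labels["id"].astype(str))
        records = []
        for seq_rec in SeqIO.parse(str(path), "fasta"):
            if seq_rec.id not in table.index:
                raise ParseError(f"{path}: FASTA id {seq_rec.id!r} missing from label CSV")
            row = table.loc[seq_rec.id]
            split = str(row["set"]) if "set" in table.columns and pd.notna(row.get("set")) else "unassigned"
            records.append(
                LabeledRecord(
                    id=seq_rec.id,
                    sequence=str(seq_rec.seq).upper(),
                    label=float(row["label"]),
                    split=split,
                )
            )
        return LabeledDataset(records, alphabet=alphabet, task=task)
    raise ParseError(f"unknown format {format!r}")


def write_dataset(dataset: LabeledDataset, path: str | Path) -> None:
    """Write the canonical CSV (id, sequence, label, set, parent_id, aug_index)."""
    dataset.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Edit distance and splitting
# ---------------------------------------------------------------------------

def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (unit-cost substitutions, insertions, deletions).

    Wagner-Fischer DP with a rolling row; no suitable edit-distance library
    ships with the environment, and the variable regions handled here are
    short enough that O(len(a) * len(b)) is negligible.
    """
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@dataclass(frozen=True)
class SplitSpec:
    """Edit-distance split: train/valid within ``ed_threshold`` of wild type,
    test beyond it; ``valid_fraction`` of the near set is held out for
    validation (stratified by label bin or class)."""

    wild_type: str
    ed_threshold: int
    valid_fraction: float = 0.2
    n_bins: int = 10

    def __post_init__(self) -> None:
        if self.ed_threshold < 1:
            raise ConfigError("ed_threshold must be >= 1")
        if not 0.0 < self.valid_fraction < 1.0:
            raise ConfigError("valid_fraction must be in (0, 1)")


def _label_strata(labels: np.ndarray, task: str, n_bins: int) -> np.ndarray:
    """Stratification key: class for classification, quantile bin for regression."""
    if task == "classification":
        return labels.astype(int)
    bins = pd.qcut(pd.Series(labels), q=min(n_bins, len(labels)), duplicates="drop", labels=False)
    return np.asarray(bins.fillna(0), dtype=int)


def split_by_edit_distance(
    dataset: LabeledDataset, spec: SplitSpec, seed: int = 0
) -> LabeledDataset:
    """Assign train/valid/test split tags by amino-acid edit distance to wild type."""
    if dataset.alphabet != "amino_acid":
        raise ConfigError("edit-distance splitting operates on amino-acid datasets")
    near_idx = []
    test_idx = []
    for i, rec in enumerate(dataset):
        if edit_distance(rec.sequence, spec.wild_type) <= spec.ed_threshold:
            near_idx.append(i)
        else:
            test_idx.append(i)
    if not near_idx or not test_idx:
        raise DegenerateSplitError(
            f"edit-distance threshold {spec.ed_threshold} leaves "
            f"{len(near_idx)} train/valid and {len(test_idx)} test records"
        )
    labels = dataset.labels[near_idx]
    strata = _label_strata(labels, dataset.task, spec.n_bins)
    # Guard against singleton strata, which sklearn's stratified splitter rejects.
    counts = pd.Series(strata).value_counts()
    if (counts < 2).any():
        strata = None
    train_pos, valid_pos = train_test_split(
        np.arange(len(near_idx)),
        test_size=spec.valid_fraction,
        random_state=seed,
        stratify=strata,
    )
    tags = {}
    for p in train_pos:
        tags[near_idx[p]] = "train"
    for p in valid_pos:
        tags[near_idx[p]] = "valid"
    for i in test_idx:
        tags[i] = "test"
    return dataset.replace_records(
        rec.with_(split=tags[i]) for i, rec in enumerate(dataset)
    )


# ---------------------------------------------------------------------------
# Truncation and imbalance
# ---------------------------------------------------------------------------

def stratified_truncate(
    train: LabeledDataset, fraction: float, n_bins: int = 10, seed: int = 0
) -> LabeledDataset:
    """Down-sample a regression training set to ``fraction`` of its records,
    preserving the fitness-bin proportions.

    Labels are cut into quantile bins (duplicate edges merged); per-bin quotas
    are apportioned by the largest-remainder method so the output size is
    exactly ``ceil(fraction * n)``; within bins records are drawn without
    replacement with the seeded generator. ``fraction == 1`` returns the input
    unchanged.
    """
    if not 0.0 < fraction <= 1.0:
        raise ConfigError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return train
    n = len(train)
    target = int(np.ceil(fraction * n))
    strata = _label_strata(train.labels, "regression", n_bins)
    rng = np.random.default_rng(seed)
    bin_ids = np.unique(strata)
    quotas = {b: fraction * int((strata == b).sum()) for b in bin_ids}
    floors = {b: int(np.floor(q)) for b, q in quotas.items()}
    shortfall = target - sum(floors.values())
    # Largest-remainder: hand out the leftover records to the biggest remainders.
    by_remainder = sorted(bin_ids, key=lambda b: (-(quotas[b] - floors[b]), int(b)))
    for b in by_remainder[:shortfall]:
        floors[b] += 1
    keep: list[int] = []
    for b in bin_ids:
        members = np.flatnonzero(strata == b)
        take = floors[b]
        if take > len(members):
            warnings.warn(
                f"fitness bin {b} has only {len(members)} records for a quota of {take}",
                NtaugWarning,
                stacklevel=2,
            )
            take = len(members)
        keep.extend(rng.choice(members, size=take, replace=False))
    keep.sort()
    return train.replace_records(train[i] for i in keep)


def impose_class_imbalance(
    train: LabeledDataset, positive_ratio: float, seed: int = 0
) -> LabeledDataset:
    """Down-sample positives to ``round(positive_ratio * n_negatives)``.

    Negatives are untouched. A ratio of 1.0 on a balanced input is the
    identity.
    """
    if train.task != "classification":
        raise ConfigError("class imbalance applies to classification datasets")
    if not 0.0 < positive_ratio <= 1.0:
        raise ConfigError(f"positive_ratio must be in (0, 1], got {positive_ratio}")
    pos = [i for i, r in enumerate(train) if r.label == 1.0]
    neg = [i for i, r in enumerate(train) if r.label == 0.0]
    if not pos or not neg:
        raise ConfigError("both classes must be present")
    n_keep = round(positive_ratio * len(neg))
    if n_keep > len(pos):
        raise InfeasibleRatioError(
            f"ratio {positive_ratio} requires {n_keep} positives but only "
            f"{len(pos)} are available"
        )
    rng = np.random.default_rng(seed)
    kept = set(rng.choice(pos, size=n_keep, replace=False))
    return train.replace_records(
        r for i, r in enumerate(train) if r.label == 0.0 or i in kept
    )


def augment_minority_class(
    train: LabeledDataset,
    cfg: AugmentationConfig,
    minority_label: float | None = None,
) -> LabeledDataset:
    """Augment only the minority class; reverse translate the majority once each.

    The minority class is the less frequent label (a tie requires an explicit
    ``minority_label``). Minority records are expanded ``n_aug``-fold with the
    configured offline method; majority records are reverse translated a
    single time each by random codon sampling (seeded).
    """
    if train.task != "classification":
        raise ConfigError("minority-class augmentation applies to classification datasets")
    if train.alphabet != "amino_acid":
        raise ConfigError("minority-class augmentation expects an amino-acid dataset")
    n_pos = sum(1 for r in train if r.label == 1.0)
    n_neg = len(train) - n_pos
    if minority_label is None:
        if n_pos == n_neg:
            raise AmbiguousMinorityError(
                "class counts are tied; pass minority_label explicitly"
            )
        minority_label = 1.0 if n_pos < n_neg else 0.0
    minority = train.replace_records(r for r in train if r.label == minority_label)
    majority = train.replace_records(r for r in train if r.label != minority_label)
    aug_minority = augment_dataset_offline(minority, cfg)
    base_cfg = AugmentationConfig(n_aug=1, method="random", table=cfg.table, seed=cfg.seed + 1)
    rt_majority = augment_dataset_offline(majority, base_cfg)
    return LabeledDataset(
        list(aug_minority) + list(rt_majority), alphabet="nucleotide", task="classification"
    )


# ---------------------------------------------------------------------------
# Test replicates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestReplicateSet:
    """Five (by default) nucleotide realizations of one amino-acid test set.

    All replicates share protein identities and order; under random codon
    sampling they differ in codon composition, capturing the reverse-
    translation variability that test metrics are averaged over.
    """

    replicates: tuple[LabeledDataset, ...]
    base_seed: int


def make_test_replicates(
    test: LabeledDataset,
    table: CodonTable,
    mode: str = "random",
    base_seed: int = 0,
    k: int = 5,
) -> TestReplicateSet:
    """Reverse translate a test set ``k`` times (replicate i seeded base_seed+i).

    ``mode`` mirrors the training setup's codon sampling: ``deterministic``
    (iterative-style) yields ``k`` identical replicates; ``random`` yields
    independent codon draws per replicate.
    """
    if test.alphabet != "amino_acid":
        raise ConfigError("test replication expects an amino-acid dataset")
    replicates = []
    for i in range(k):
        rng = np.random.default_rng(base_seed + i)
        records = [
            rec.with_(
                sequence=codon_model.reverse_translate(rec.sequence, table, mode, rng),
                parent_id=rec.id,
            )
            for rec in test
        ]
        replicates.append(LabeledDataset(records, alphabet="nucleotide", task=test.task))
    return TestReplicateSet(replicates=tuple(replicates), base_seed=base_seed)
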