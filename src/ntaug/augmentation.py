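"""Nucleotide augmentation: offline iterative, offline random, online probabilistic.

Offline augmentation expands a stored amino-acid training set into ``n_aug``
synonymous nucleotide sequences per record before training:

* *iterative* — deterministic. The base sequence uses the lexicographically
  first codon of every residue; subsequent augmentations walk the cartesian
  product of per-position codon choices with the leftmost position varying
  fastest, so early augmentations differ from the base only near the
  sequence start.
* *random* — every augmentation draws each residue's codon uniformly and
  independently; duplicates can occur and are kept (with a warning), which is
  what uniform sampling of a finite synonym space naturally produces.

Online augmentation leaves the dataset size unchanged and instead perturbs
mini-batches during training: per sequence a modification probability
``p_aug ~ U(0,1)`` is drawn and, when it exceeds the threshold ``t_aug``, up
to ``floor(num_subs * n_codons)`` codons are swapped for synonymous
alternatives.

Every augmented sequence translates back to its parent amino-acid sequence
and inherits the parent's label unchanged.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import codon_model
from .codon_model import CodonTable
from .dataset import LabeledDataset, LabeledRecord
from .errors import AugmentationWarning, ConfigError

__all__ = [
    "AugmentationConfig",
    "OnlineAugmentConfig",
    "augment_offline_iterative",
    "augment_offline_random",
    "augment_dataset_offline",
    "augment_online_batch",
]


@dataclass(frozen=True)
class AugmentationConfig:
    """Offline augmentation settings.

    ``n_aug`` is the augmentation factor: the number of nucleotide sequences
    emitted per amino-acid record (capacity permitting for the iterative
    method).
    """

    n_aug: int
    method: Literal["iterative", "random"]
    table: CodonTable = field(default_factory=codon_model.natural_table)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_aug < 1:
            raise ConfigError(f"n_aug must be >= 1, got {self.n_aug}")
        if self.method not in ("iterative", "random"):
            raise ConfigError(f"unknown offline method {self.method!r}")


@dataclass(frozen=True)
class OnlineAugmentConfig:
    """Online (mini-batch) augmentation settings.

    ``t_aug`` is the modification threshold (a sequence is modified when its
    fresh ``p_aug`` draw strictly exceeds it; 0.5 in the experiments this
    package reproduces) and ``num_subs`` caps the fraction of codon positions
    substituted per modification (0.25 by default).
    """

    t_aug: float = 0.5
    num_subs: float = 0.25
    table: CodonTable = field(default_factory=codon_model.natural_table)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_aug <= 1.0:
            raise ConfigError(f"t_aug must be in [0, 1], got {self.t_aug}")
        if not 0.0 < self.num_subs <= 1.0:
            raise ConfigError(f"num_subs must be in (0, 1], got {self.num_subs}")


def _as_augmented_record(parent: LabeledRecord, nt: str, i: int) -> LabeledRecord:
    return LabeledRecord(
        id=f"{parent.id}|aug{i}",
        sequence=nt,
        label=parent.label,
        split=parent.split,
        parent_id=parent.id,
        aug_index=i,
    )


def augment_offline_iterative(
    record: LabeledRecord, cfg: AugmentationConfig
) -> list[LabeledRecord]:
    """Deterministically enumerate up to ``n_aug`` synonymous sequences.

    Output 0 is the deterministic reverse translation; outputs 1.. follow the
    cartesian-product order (leftmost codon position varying fastest). When
    ``n_aug`` exceeds the synonym capacity the output is capped at capacity,
    with a warning — enumeration cannot mint new distinct sequences.
    """
    capacity = codon_model.synonym_capacity(record.sequence, cfg.table)
    if cfg.n_aug > capacity:
        warnings.warn(
            f"record {record.id!r}: n_aug={cfg.n_aug} exceeds synonym capacity "
            f"{capacity}; emitting {capacity} sequences",
            AugmentationWarning,
            stacklevel=2,
        )
    synonyms = itertools.islice(
        codon_model.enumerate_synonyms(record.sequence, cfg.table),
        min(cfg.n_aug, capacity),
    )
    return [_as_augmented_record(record, nt, i) for i, nt in enumerate(synonyms)]


def augment_offline_random(
    record: LabeledRecord,
    cfg: AugmentationConfig,
    rng: np.random.Generator | None = None,
) -> list[LabeledRecord]:
    """Draw exactly ``n_aug`` random reverse translations (duplicates allowed)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    out = []
    for i in range(cfg.n_aug):
        nt = codon_model.reverse_translate(record.sequence, cfg.table, "random", rng)
        out.append(_as_augmented_record(record, nt, i))
    seen = {r.sequence for r in out}
    if len(seen) < len(out):
        warnings.warn(
            f"record {record.id!r}: random augmentation produced "
            f"{len(out) - len(seen)} duplicate sequence(s)",
            AugmentationWarning,
            stacklevel=2,
        )
    return out


def augment_dataset_offline(
    dataset: LabeledDataset, cfg: AugmentationConfig
) -> LabeledDataset:
    """Augment every record of an amino-acid dataset; returns a nucleotide dataset.

    Output order is stable: input order, then augmentation index. Random-mode
    draws use an independent seeded stream per record (derived from
    ``cfg.seed`` and the record's position) so one record's output does not
    depend on another's synonym capacity.
    """
    if dataset.alphabet != "amino_acid":
        raise ConfigError("offline augmentation expects an amino-acid dataset")
    records: list[LabeledRecord] = []
    for idx, rec in enumerate(dataset):
        if cfg.method == "iterative":
            records.extend(augment_offline_iterative(rec, cfg))
        else:
            rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, idx]))
            records.extend(augment_offline_random(rec, cfg, rng))
    return LabeledDataset(records, alphabet="nucleotide", task=dataset.task)


def augment_online_batch(
    batch: Sequence[str],
    cfg: OnlineAugmentConfig,
    rng: np.random.Generator,
) -> list[str]:
    """Probabilistically substitute synonymous codons in a mini-batch.

    For each sequence a fresh ``p_aug ~ U(0,1)`` is drawn; if ``p_aug >
    t_aug`` the sequence is modified: ``k`` is drawn uniformly from
    ``{1, ..., max(1, floor(num_subs * n_codons))}``, ``k`` codon positions
    with degeneracy >= 2 are chosen uniformly without replacement (fewer if
    the sequence has fewer such positions; unchanged if it has none), and
    each chosen codon is replaced by a uniform draw over its synonymous
    alternatives excluding itself. Batch size, ordering and (implicitly)
    labels are untouched; every output translates to the same protein as its
    input.
    """
    out = []
    for seq in batch:
        p_aug = float(rng.uniform())
        if p_aug <= cfg.t_aug:
            out.append(seq)
            continue
        aa = codon_model.translate(seq, cfg.table)  # validates codon alignment
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        eligible = [i for i, r in enumerate(aa) if cfg.table.degeneracy(r) >= 2]
        if not eligible:
            out.append(seq)
            continue
        k_max = max(1, int(cfg.num_subs * len(codons)))
        k = int(rng.integers(1, k_max + 1))
        k = min(k, len(eligible))
        positions = rng.choice(len(eligible), size=k, replace=False)
        for pos in (eligible[int(p)] for p in positions):
            alternatives = [c for c in cfg.table.codons(aa[pos]) if c != codons[pos]]
            codons[pos] = alternatives[int(rng.integers(len(alternatives)))]
        out.append("".join(codons))
    return out
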