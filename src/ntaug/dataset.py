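"""Labeled sequence datasets.

A :class:`LabeledDataset` is an ordered collection of records, each a
sequence (amino acid or nucleotide) with a label — a continuous fitness value
for regression or a 0/1 class for classification — plus provenance fields
(parent id and augmentation index for augmented records) and a split tag.
It converts to/from a pandas DataFrame, which is also the on-disk CSV layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Literal

import numpy as np
import pandas as pd

from .errors import ParseError

__all__ = ["LabeledRecord", "LabeledDataset", "SPLITS"]

SPLITS = ("train", "valid", "test", "unassigned")

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
_NT_ALPHABET = set("ACGT")


@dataclass(frozen=True)
class LabeledRecord:
    id: str
    sequence: str
    label: float
    split: str = "unassigned"
    parent_id: str | None = None
    aug_index: int | None = None

    def with_(self, **kwargs) -> "LabeledRecord":
        return replace(self, **kwargs)


@dataclass
class LabeledDataset:
    """Ordered labeled records with a declared alphabet and task.

    Invariants (checked on construction): unique ids; sequences over the
    declared alphabet; classification labels in {0, 1}; split tags valid.
    """

    records: list[LabeledRecord]
    alphabet: Literal["amino_acid", "nucleotide"]
    task: Literal["regression", "classification"]
    _validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        if self.alphabet not in ("amino_acid", "nucleotide"):
            raise ParseError(f"unknown alphabet {self.alphabet!r}")
        if self.task not in ("regression", "classification"):
            raise ParseError(f"unknown task {self.task!r}")
        if not self._validate:
            return
        seen: set[str] = set()
        allowed = _AA_ALPHABET if self.alphabet == "amino_acid" else _NT_ALPHABET
        for i, rec in enumerate(self.records):
            if rec.id in seen:
                raise ParseError(f"duplicate record id {rec.id!r} (record {i})")
            seen.add(rec.id)
            bad = set(rec.sequence) - allowed
            if bad:
                raise ParseError(
                    f"record {rec.id!r}: characters {sorted(bad)} outside the "
                    f"{self.alphabet} alphabet"
                )
            if rec.split not in SPLITS:
                raise ParseError(f"record {rec.id!r}: unknown split tag {rec.split!r}")
            if self.task == "classification" and rec.label not in (0.0, 1.0):
                raise ParseError(
                    f"record {rec.id!r}: classification label must be 0 or 1, got {rec.label}"
                )

    # -- container protocol -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LabeledRecord]:
        return iter(self.records)

    def __getitem__(self, i) -> LabeledRecord:
        return self.records[i]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=float)

    def subset(self, split: str) -> "LabeledDataset":
        """Records carrying the given split tag, in original order."""
        return self.replace_records([r for r in self.records if r.split == split])

    def replace_records(self, records: Iterable[LabeledRecord]) -> "LabeledDataset":
        return LabeledDataset(list(records), self.alphabet, self.task, _validate=False)

    # -- DataFrame bridge ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "sequence": [r.sequence for r in self.records],
                "label": [r.label for r in self.records],
                "set": [r.split for r in self.records],
                "parent_id": [r.parent_id for r in self.records],
                "aug_index": [r.aug_index for r in self.records],
            }
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        alphabet: str,
        task: str,
    ) -> "LabeledDataset":
        if "sequence" not in frame.columns or "label" not in frame.columns:
            missing = {"sequence", "label"} - set(frame.columns)
            raise ParseError(f"missing required column(s): {sorted(missing)}")
        records = []
        for i, row in enumerate(frame.itertuples(index=False)):
            rec_id = str(getattr(row, "id", "")) if "id" in frame.columns else f"seq{i}"
            try:
                label = float(row.label)
            except (TypeError, ValueError):
                raise ParseError(
                    f"row {i + 1}: label {row.label!r} is not numeric"
                ) from None
            split = str(getattr(row, "set", "unassigned") or "unassigned") if "set" in frame.columns else "unassigned"
            parent = getattr(row, "parent_id", None) if "parent_id" in frame.columns else None
            if parent is not None and (parent != parent or parent == ""):  # NaN/empty
                parent = None
            aug = getattr(row, "aug_index", None) if "aug_index" in frame.columns else None
            if aug is not None and aug == aug and aug != "":
                aug = int(aug)
            else:
                aug = None
            records.append(
                LabeledRecord(
                    id=rec_id,
                    sequence=str(row.sequence).upper(),
                    label=label,
                    split=split,
                    parent_id=None if parent is None else str(parent),
                    aug_index=aug,
                )
            )
        return cls(records, alphabet, task)
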