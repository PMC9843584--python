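"""Amino-acid-to-codon relationships and reverse-translation primitives.

Nucleotide augmentation rests on codon degeneracy: each of the 20 canonical
amino acids is encoded by 1-6 trinucleotide codons (61 sense codons in the
standard genetic code), so one protein sequence corresponds to a
combinatorially large family of synonymous nucleotide sequences. This module
defines the codon-table data structure and three concrete relationships:

``natural``
    The standard genetic code restricted to sense codons (stop codons are
    never used: only coding sequence is augmented).
``balanced``
    A synthetic "codon balance" table giving every amino acid exactly three
    codons (60 codons used), removing the uneven degeneracy of the natural
    code.
``shuffled``
    A "codon shuffle" table that permutes which codons encode which amino
    acid while conserving the per-amino-acid degeneracy counts of the
    natural code.

On top of the tables it provides translation, deterministic and random
reverse translation, and synonym-space counting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
from Bio.Data import CodonTable as _BioCodonTable

from .errors import (
    MalformedSequenceError,
    UnsupportedResidueError,
    UntranslatableCodonError,
)

__all__ = [
    "AMINO_ACIDS",
    "CodonTable",
    "natural_table",
    "balanced_table",
    "shuffled_table",
    "translate",
    "reverse_translate",
    "synonym_capacity",
    "enumerate_synonyms",
]

#: The 20 canonical amino acids, one-letter codes, alphabetical.
AMINO_ACIDS: tuple[str, ...] = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))

_BASES = "ACGT"


def _validate_aa(aa: str) -> str:
    aa = aa.upper()
    if not aa:
        raise UnsupportedResidueError("empty amino-acid sequence")
    bad = set(aa) - set(AMINO_ACIDS)
    if bad:
        raise UnsupportedResidueError(
            f"non-canonical residue(s) {sorted(bad)} in sequence; only the 20 "
            "canonical amino acids can be reverse translated"
        )
    return aa


@dataclass(frozen=True)
class CodonTable:
    """An amino-acid -> codon-list mapping with a functional reverse lookup.

    Parameters
    ----------
    name
        ``"natural"``, ``"balanced"`` or ``"shuffled"``.
    mapping
        Dict keyed by the 20 canonical one-letter codes; each value is a
        lexicographically sorted, duplicate-free tuple of 3-mers over ACGT.
        No codon may appear under two amino acids.
    seed
        The seed used to build a synthetic (balanced/shuffled) table;
        ``None`` for the natural table.
    """

    name: str
    mapping: dict[str, tuple[str, ...]]
    seed: int | None = None
    _reverse: dict[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if set(self.mapping) != set(AMINO_ACIDS):
            raise ValueError("codon table must map exactly the 20 canonical amino acids")
        reverse: dict[str, str] = {}
        for aa, codons in self.mapping.items():
            if not codons:
                raise ValueError(f"empty codon list for {aa}")
            if list(codons) != sorted(set(codons)):
                raise ValueError(f"codon list for {aa} must be sorted and duplicate-free")
            for codon in codons:
                if len(codon) != 3 or set(codon) - set(_BASES):
                    raise ValueError(f"invalid codon {codon!r}")
                if codon in reverse:
                    raise ValueError(f"codon {codon} assigned to both {reverse[codon]} and {aa}")
                reverse[codon] = aa
        object.__setattr__(self, "_reverse", reverse)

    def codons(self, aa: str) -> tuple[str, ...]:
        try:
            return self.mapping[aa]
        except KeyError:
            raise UnsupportedResidueError(f"residue {aa!r} not in codon table") from None

    def amino_acid(self, codon: str) -> str | None:
        """Amino acid encoded by *codon*, or ``None`` if unassigned/stop."""
        return self._reverse.get(codon)

    def degeneracy(self, aa: str) -> int:
        return len(self.codons(aa))

    @property
    def n_codons(self) -> int:
        return sum(len(c) for c in self.mapping.values())

    # -- plain-text serialization -------------------------------------------------
    # One residue per line: "<letter><TAB><codon>,<codon>,...". This lets a user
    # drop in an externally published balance/shuffle table verbatim.

    def to_text(self) -> str:
        lines = [f"# codon table: {self.name}" + (f" (seed={self.seed})" if self.seed is not None else "")]
        for aa in AMINO_ACIDS:
            lines.append(f"{aa}\t{','.join(self.mapping[aa])}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, name: str = "custom", seed: int | None = None) -> "CodonTable":
        mapping: dict[str, tuple[str, ...]] = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                aa, codons = line.split("\t") if "\t" in line else line.split(None, 1)
            except ValueError:
                raise ValueError(f"line {lineno}: expected '<residue> <codons>'") from None
            mapping[aa.strip().upper()] = tuple(sorted(c.strip().upper() for c in codons.split(",")))
        return cls(name=name, mapping=mapping, seed=seed)


def _standard_code() -> dict[str, list[str]]:
    """Sense codons of the standard genetic code, keyed by amino acid."""
    fwd = _BioCodonTable.unambiguous_dna_by_id[1].forward_table
    out: dict[str, list[str]] = {aa: [] for aa in AMINO_ACIDS}
    for codon, aa in fwd.items():
        out[aa].append(codon)
    return {aa: sorted(codons) for aa, codons in out.items()}


def natural_table() -> CodonTable:
    """The standard genetic code (61 sense codons; stops excluded)."""
    return CodonTable(name="natural", mapping={aa: tuple(c) for aa, c in _standard_code().items()})


def balanced_table(seed: int) -> CodonTable:
    """A codon-balance table: exactly 3 codons per amino acid (60 codons used).

    Residues with three or more natural codons keep their three
    lexicographically smallest; residues with fewer keep all of theirs and are
    topped up to three from the pool of then-unassigned sense codons, drawn by
    a seeded shuffle. Deterministic in *seed*.
    """
    natural = _standard_code()
    kept = {aa: codons[:3] for aa, codons in natural.items()}
    assigned = {c for codons in kept.values() for c in codons}
    pool = sorted({c for codons in natural.values() for c in codons} - assigned)
    rng = np.random.default_rng(seed)
    rng.shuffle(pool)
    pool_iter = iter(pool)
    mapping = {}
    for aa in AMINO_ACIDS:
        codons = list(kept[aa])
        while len(codons) < 3:
            codons.append(next(pool_iter))
        mapping[aa] = tuple(sorted(codons))
    return CodonTable(name="balanced", mapping=mapping, seed=seed)


def shuffled_table(seed: int) -> CodonTable:
    """A codon-shuffle table: natural degeneracy counts, permuted codon identities.

    The 61 sense codons are permuted with a seeded shuffle and dealt back out
    in the natural per-residue counts, iterating residues alphabetically.
    """
    natural = _standard_code()
    codons = sorted(c for lst in natural.values() for c in lst)
    rng = np.random.default_rng(seed)
    rng.shuffle(codons)
    it = iter(codons)
    mapping = {
        aa: tuple(sorted(next(it) for _ in range(len(natural[aa])))) for aa in AMINO_ACIDS
    }
    return CodonTable(name="shuffled", mapping=mapping, seed=seed)


def translate(nt: str, table: CodonTable) -> str:
    """Translate a codon-aligned nucleotide sequence by reverse codon lookup."""
    nt = nt.upper()
    if len(nt) % 3 != 0:
        raise MalformedSequenceError(
            f"nucleotide sequence length {len(nt)} is not a multiple of 3"
        )
    residues = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        aa = table.amino_acid(codon)
        if aa is None:
            raise UntranslatableCodonError(codon, i // 3)
        residues.append(aa)
    return "".join(residues)


def reverse_translate(
    aa: str,
    table: CodonTable,
    mode: Literal["deterministic", "random"] = "deterministic",
    rng: np.random.Generator | None = None,
) -> str:
    """Reverse translate an amino-acid sequence into one nucleotide sequence.

    ``deterministic`` mode always picks the lexicographically first codon of
    each residue (the same codon every time, so identical proteins map to
    identical DNA); ``random`` mode draws each residue's codon uniformly and
    independently from its codon list using *rng*.
    """
    aa = _validate_aa(aa)
    if mode == "deterministic":
        return "".join(table.codons(r)[0] for r in aa)
    if mode == "random":
        if rng is None:
            raise ValueError("random mode requires an rng")
        parts = []
        for r in aa:
            codons = table.codons(r)
            parts.append(codons[int(rng.integers(len(codons)))])
        return "".join(parts)
    raise ValueError(f"unknown mode {mode!r}")


def synonym_capacity(aa: str, table: CodonTable) -> int:
    """Number of distinct synonymous nucleotide sequences encoding *aa*.

    The product over residues of each residue's codon-list length.
    """
    aa = _validate_aa(aa)
    capacity = 1
    for r in aa:
        capacity *= table.degeneracy(r)
    return capacity


def enumerate_synonyms(aa: str, table: CodonTable) -> Iterator[str]:
    """Yield every synonymous nucleotide sequence of *aa* (leftmost codon fastest).

    The iteration order matches offline iterative augmentation: the cartesian
    product of per-position codon lists with the leftmost position varying
    fastest, starting from the all-lexicographic-first base sequence.
    """
    aa = _validate_aa(aa)
    choices = [table.codons(r) for r in aa]
    # itertools.product varies the *last* iterable fastest; reverse in and out
    # to make the leftmost codon position the fast axis.
    for combo in itertools.product(*reversed(choices)):
        yield "".join(reversed(combo))
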