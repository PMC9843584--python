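"""ngram tokenization and categorical / one-hot encoding of sequences.

Four schemes are supported:

=================  ==========================================  ============
scheme             tokens                                      vocabulary
=================  ==========================================  ============
``aa_unigram``     one token per residue                       21 (20 + UNK)
``nt_unigram``     one token per base                          4
``nt_trigram``     non-overlapping codons                      64
``nt_tri_unigram`` trigram tokens followed by unigram tokens   68
=================  ==========================================  ============

Vocabularies are closed (alphabet-derived), not fitted from data. Token ids
start at 1; id 0 is the reserved PAD id, which is not a content token.
Categorical id matrices feed the transformer models; an additional one-hot
step produces CNN input. A boolean mask marks PAD positions so models can
ignore them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, EncodingError, MalformedSequenceError
from .codon_model import AMINO_ACIDS

__all__ = [
    "SCHEMES",
    "PAD_ID",
    "UNK",
    "Vocabulary",
    "TokenizedSequence",
    "EncodedBatch",
    "tokenize",
    "build_vocabulary",
    "encode_categorical",
    "encode_one_hot",
    "encode_sequences",
]

SCHEMES = ("aa_unigram", "nt_unigram", "nt_trigram", "nt_tri_unigram")
PAD_ID = 0
UNK = "UNK"

_BASES = tuple("ACGT")
_TRIGRAMS = tuple("".join(p) for p in product("ACGT", repeat=3))


@dataclass(frozen=True)
class Vocabulary:
    """Closed token inventory for one encoding scheme.

    ``tokens`` lists content tokens only, in their fixed id order; token ids
    are ``index + 1`` because id 0 is PAD. ``content_size`` therefore excludes
    PAD (4, 64, 68 or 21 depending on scheme).
    """

    scheme: str
    tokens: tuple[str, ...]
    _ids: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_ids", {t: i + 1 for i, t in enumerate(self.tokens)})

    @property
    def content_size(self) -> int:
        return len(self.tokens)

    def token_id(self, token: str) -> int:
        try:
            return self._ids[token]
        except KeyError:
            if self.scheme == "aa_unigram":
                return self._ids[UNK]
            raise EncodingError(f"token {token!r} not in {self.scheme} vocabulary") from None


@dataclass(frozen=True)
class TokenizedSequence:
    tokens: tuple[str, ...]
    scheme: str
    source_length: int


@dataclass(frozen=True)
class EncodedBatch:
    """Padded id matrix (batch x max_len), optional one-hot, and PAD mask.

    ``mask`` is True exactly at PAD positions. Non-PAD rows of ``one_hot``
    are unit vectors over the content vocabulary; PAD rows are all zero.
    """

    token_ids: np.ndarray
    mask: np.ndarray
    one_hot: np.ndarray | None = None


def build_vocabulary(scheme: str) -> Vocabulary:
    """The full closed vocabulary for a scheme, in fixed lexicographic order.

    For ``nt_tri_unigram`` the 68 tokens (64 trigrams + 4 unigrams) are sorted
    together lexicographically; for ``aa_unigram`` the 20 canonical residues
    are followed by the UNK token in last place.
    """
    if scheme == "nt_unigram":
        return Vocabulary(scheme, _BASES)
    if scheme == "nt_trigram":
        return Vocabulary(scheme, _TRIGRAMS)
    if scheme == "nt_tri_unigram":
        return Vocabulary(scheme, tuple(sorted(_TRIGRAMS + _BASES)))
    if scheme == "aa_unigram":
        return Vocabulary(scheme, AMINO_ACIDS + (UNK,))
    raise ConfigError(f"unknown encoding scheme {scheme!r}; expected one of {SCHEMES}")


def tokenize(seq: str, scheme: str) -> TokenizedSequence:
    """Break a sequence into the scheme's ngram token list.

    Trigram-bearing schemes require the nucleotide length to be a multiple of
    3 (non-overlapping codons). ``nt_tri_unigram`` concatenates the trigram
    token list with the unigram token list, giving L/3 + L tokens.
    """
    seq = seq.upper()
    if scheme == "aa_unigram":
        return TokenizedSequence(tuple(seq), scheme, len(seq))
    if scheme not in SCHEMES:
        raise ConfigError(f"unknown encoding scheme {scheme!r}")
    bad = set(seq) - set("ACGT")
    if bad:
        raise EncodingError(
            f"character(s) {sorted(bad)} outside the nucleotide alphabet"
        )
    if scheme == "nt_unigram":
        return TokenizedSequence(tuple(seq), scheme, len(seq))
    if len(seq) % 3 != 0:
        raise MalformedSequenceError(
            f"length {len(seq)} not divisible by 3; {scheme} requires codon-aligned input"
        )
    trigrams = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
    if scheme == "nt_trigram":
        return TokenizedSequence(trigrams, scheme, len(seq))
    return TokenizedSequence(trigrams + tuple(seq), scheme, len(seq))


def encode_categorical(
    batch: Sequence[TokenizedSequence],
    vocab: Vocabulary,
    max_len: int | None = None,
) -> EncodedBatch:
    """Map token lists to a PAD-filled id matrix plus PAD mask.

    Rows are padded to ``max_len`` (default: the batch's longest token list).
    """
    lengths = [len(ts.tokens) for ts in batch]
    width = max(lengths, default=0) if max_len is None else max_len
    if any(n > width for n in lengths):
        raise EncodingError(f"sequence of {max(lengths)} tokens exceeds max_len={width}")
    ids = np.full((len(batch), width), PAD_ID, dtype=np.int64)
    for i, ts in enumerate(batch):
        if ts.scheme != vocab.scheme:
            raise EncodingError(
                f"sequence tokenized as {ts.scheme} cannot be encoded with a "
                f"{vocab.scheme} vocabulary"
            )
        for j, tok in enumerate(ts.tokens):
            ids[i, j] = vocab.token_id(tok)
    return EncodedBatch(token_ids=ids, mask=ids == PAD_ID)


def encode_one_hot(encoded: EncodedBatch, vocab: Vocabulary) -> EncodedBatch:
    """Add a one-hot tensor (batch x max_len x content_size) to an encoded batch."""
    if encoded.token_ids is None:  # pragma: no cover - contract guard
        raise ConfigError("encode_one_hot requires token_ids")
    ids = encoded.token_ids
    one_hot = np.zeros(ids.shape + (vocab.content_size,), dtype=np.float64)
    rows, cols = np.nonzero(ids != PAD_ID)
    one_hot[rows, cols, ids[rows, cols] - 1] = 1.0
    return EncodedBatch(token_ids=ids, mask=encoded.mask, one_hot=one_hot)


def encode_sequences(
    sequences: Iterable[str],
    scheme: str,
    vocab: Vocabulary | None = None,
    max_len: int | None = None,
    one_hot: bool = False,
) -> EncodedBatch:
    """Convenience: tokenize + categorical (+ optional one-hot) in one call."""
    vocab = vocab or build_vocabulary(scheme)
    batch = encode_categorical([tokenize(s, scheme) for s in sequences], vocab, max_len)
    return encode_one_hot(batch, vocab) if one_hot else batch


def n_tokens(source_length: int, scheme: str) -> int:
    """Closed-form token count for a sequence of the given length."""
    if scheme in ("aa_unigram", "nt_unigram"):
        return source_length
    if scheme == "nt_trigram":
        return source_length // 3
    if scheme == "nt_tri_unigram":
        return source_length // 3 + source_length
    raise ConfigError(f"unknown encoding scheme {scheme!r}")
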