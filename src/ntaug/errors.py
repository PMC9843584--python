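"""Exception and warning hierarchy for ntaug.

All package-level failures derive from :class:`NtaugError` so callers can
catch one base class; the CLI maps config errors to exit code 2 and data
errors to exit code 3.
"""


class NtaugError(Exception):
    """Base class for all ntaug errors."""


class ConfigError(NtaugError):
    """Invalid configuration (bad scheme/family combination, schema violation)."""


class DataError(NtaugError):
    """Base class for dataset / sequence-content errors."""


class ParseError(DataError):
    """Malformed input file (missing columns, bad labels, duplicate ids)."""


class MalformedSequenceError(DataError):
    """Sequence violates a structural precondition (e.g. length not a multiple of 3)."""


class UnsupportedResidueError(DataError):
    """Amino-acid sequence contains a non-canonical letter (including UNK)."""


class UntranslatableCodonError(DataError):
    """A codon has no amino-acid assignment under the active codon table."""

    def __init__(self, codon: str, position: int):
        self.codon = codon
        self.position = position
        super().__init__(
            f"codon {codon!r} at codon position {position} has no amino-acid "
            "assignment under this table"
        )


class DegenerateSplitError(DataError):
    """Edit-distance split produced an empty train or test partition."""


class InfeasibleRatioError(DataError):
    """Requested class-imbalance ratio needs more records than are available."""


class AmbiguousMinorityError(DataError):
    """Class counts are tied; the minority class must be named explicitly."""


class CapacityError(DataError):
    """More distinct variants requested than the sequence space contains."""


class EncodingError(DataError):
    """Token outside the scheme's vocabulary."""


class UndefinedMetricError(NtaugError):
    """Metric undefined for this input (e.g. Spearman on a constant vector)."""


class AggregationError(NtaugError):
    """Replicate/seed result lists are inconsistent and cannot be aggregated."""


class NtaugWarning(UserWarning):
    """Base warning class."""


class AugmentationWarning(NtaugWarning):
    """Duplicate augmented sequences, or n_aug exceeding synonym capacity."""
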