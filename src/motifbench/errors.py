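"""Exception hierarchy shared across the package."""


class MotifBenchError(Exception):
    """Base class for all package errors."""


class MalformedMotifError(MotifBenchError):
    """A motif block violates the format contract (e.g. a bad row sum)."""


class InvalidBackgroundError(MotifBenchError):
    """A background distribution contains a zero (or negative) entry."""


class SequenceTooShortError(MotifBenchError):
    """A sequence is shorter than the motif scanned against it."""


class MalformedIntervalError(MotifBenchError):
    """A genomic interval with end <= start, or an unparseable line."""


class UnknownChromosomeError(MotifBenchError):
    """A peak references a chromosome absent from the genome."""


class UndefinedOverlapError(MotifBenchError):
    """Overlap percentage requested for an empty peak set."""


class UndefinedProfileError(MotifBenchError):
    """ERE profile requested for an empty peak set."""


class InsufficientProteinsError(MotifBenchError):
    """Matched/unmatched decomposition needs at least two shared proteins."""


class UndefinedAUROCError(MotifBenchError):
    """AUROC requested with an empty positive or negative score list."""


class EvaluationImpossibleError(MotifBenchError):
    """No peak window is long enough for the motif being evaluated."""


class BackgroundTooShortError(MotifBenchError):
    """Similarity background sequences shorter than a motif."""


class UnselectableProteinError(MotifBenchError):
    """No candidate motif for a protein carries any defined AUROC."""


class PoolExhaustedError(MotifBenchError):
    """A peak-set draw requests more true sites than the pool holds."""


class OvercrowdedGenomeError(MotifBenchError):
    """Non-overlapping placement of repeat copies failed repeatedly."""


class ConfigError(MotifBenchError):
    """An unknown or unparseable configuration key/value."""
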