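"""Exception hierarchy shared across the package."""


class CodonHegError(Exception):
    """Base class for all errors raised by codonheg."""


class FormatError(CodonHegError, ValueError):
    """A file does not conform to the expected format (FASTA, PTT, ...)."""


class UsageError(CodonHegError, ValueError):
    """An operation was invoked with unusable arguments."""


class ExtractionError(CodonHegError, ValueError):
    """Gene coordinates are inconsistent with the attached genome."""


class NoHegGenesError(CodonHegError):
    """No highly-expressed-gene catalog entry matched the annotation table."""


class ProfileError(CodonHegError, ValueError):
    """A pair of codon-usage profiles cannot be correlated."""
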