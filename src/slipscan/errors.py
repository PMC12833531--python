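"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`SlipscanError`, so callers (and the CLI) can distinguish operational
failures from programming errors.
"""


class SlipscanError(Exception):
    """Base class for all errors raised by slipscan."""


class FastaParseError(SlipscanError):
    """Malformed FASTA input; ``line`` is the 1-based offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class SequenceValidationError(SlipscanError):
    """Illegal residue; ``position`` is the 0-based offset of the character."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        super().__init__(message)


class FrameError(SlipscanError):
    """Sequence length is not a multiple of three."""


class IntegrityError(SlipscanError):
    """A site object is inconsistent with the sequence it claims to index."""


class TranslationError(SlipscanError):
    """Untranslatable codon; ``position`` is the 0-based codon start."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        super().__init__(message)


class FixtureError(SlipscanError):
    """Synthetic-fixture generation or planting could not satisfy its spec."""
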