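"""Exception hierarchy shared across the package."""


class SecdegError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SecdegError):
    """An input file does not conform to the expected table dialect."""


class RowParseError(FormatError):
    """A single data row could not be parsed; carries the 1-based file line."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class DesignError(SecdegError):
    """A plex design violates its invariants."""


class DesignMismatchError(SecdegError):
    """A PSM table and the plex design disagree (channels, fractions)."""


class MappingError(SecdegError):
    """A peptide does not map to its protein at the stated coordinates."""


class MissingProteinError(MappingError):
    """An accession referenced by a peptide is absent from the proteome."""


class CoordinateError(SecdegError, ValueError):
    """A protein coordinate falls outside the valid range."""


class ConfigError(SecdegError, ValueError):
    """Invalid simulation or pipeline configuration."""


class NonSpecificPeptideError(SecdegError):
    """Neither peptide terminus is tryptic-specific; flags an upstream
    inconsistency (a semi-specific search should never emit such peptides)."""


class HyperparameterError(SecdegError):
    """The empirical-Bayes variance prior could not be estimated."""


class StageError(SecdegError):
    """A pipeline stage failed; names the stage and the offending record."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
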