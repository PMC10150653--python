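"""Exception hierarchy.

Every error raised by the package derives from :class:`EmtStratError`, so
callers (and the CLI) can distinguish configuration problems, malformed
input files and statistical edge cases from programming errors.
"""


class EmtStratError(Exception):
    """Base class for all package errors."""


class ConfigError(EmtStratError):
    """Invalid configuration (thresholds, simulation parameters, run config)."""


class FormatError(EmtStratError):
    """Malformed input file: dimension mismatch, non-numeric cell, bad header."""


class DuplicateIDError(EmtStratError):
    """Duplicate observation or gene identifiers (possibly after symbol
    normalisation); the offending identifiers are listed in the message."""

    def __init__(self, kind: str, offenders):
        self.kind = kind
        self.offenders = sorted(set(offenders))
        super().__init__(f"duplicate {kind} identifiers: {', '.join(self.offenders)}")


class ValidationError(EmtStratError):
    """Semantically invalid domain object (e.g. a gene in both roles of one
    signature, an empty signature)."""


class MissingGeneError(EmtStratError):
    """A required gene is absent from the expression matrix."""

    def __init__(self, genes, context: str = ""):
        self.genes = sorted(set(genes))
        msg = f"missing gene(s): {', '.join(self.genes)}"
        if context:
            msg = f"{context}: {msg}"
        super().__init__(msg)


class InsufficientDataError(EmtStratError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(EmtStratError):
    """Data admit no meaningful test (all paired differences zero, constant
    variable in a correlation)."""
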