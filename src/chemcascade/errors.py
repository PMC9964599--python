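"""Exception hierarchy for the screening cascade."""


class CascadeError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CascadeError):
    """A SMILES (or SDF block) could not be parsed into a valid molecule.

    Carries the offending input string as ``.offending``.
    """

    def __init__(self, message: str, offending: str = ""):
        super().__init__(message)
        self.offending = offending


class EmbedError(CascadeError):
    """3D conformer embedding failed after retries."""


class KeyMissingError(CascadeError, KeyError):
    """A compound/drug/target id could not be resolved in a lookup table."""


class IncompatibleFingerprintError(CascadeError):
    """Tanimoto requested between fingerprints of different kind or length."""


class InsufficientDataError(CascadeError):
    """Too few paired observations for the requested statistic."""


class UndefinedCorrelationError(CascadeError):
    """Correlation undefined: one of the vectors has zero variance."""


class DuplicateKeyError(CascadeError):
    """Records violated a dedup-before-join precondition."""


class DomainError(CascadeError, ValueError):
    """A value lies outside the domain of the operation (e.g. potency <= 0)."""
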