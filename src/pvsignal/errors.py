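"""Exception hierarchy for the pvsignal pipeline."""


class PvSignalError(Exception):
    """Base class for all pvsignal errors."""


class ConfigurationError(PvSignalError):
    """A generator or pipeline configuration field is invalid."""


class FormatError(PvSignalError):
    """An input table is malformed (e.g. a required column is absent)."""


class CatalogLookupError(PvSignalError):
    """A drug, preferred term, or hierarchy term is unknown."""


class DegenerateInputError(PvSignalError):
    """An operation received an empty or otherwise degenerate input."""


class InsufficientDataError(PvSignalError):
    """Too few complete observations to compute a statistic."""


class DomainError(PvSignalError):
    """A value lies outside the mathematical domain of an operation
    (e.g. a non-positive Ki)."""
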