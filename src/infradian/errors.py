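"""Exception hierarchy for the infradian package."""


class InfradianError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(InfradianError, ValueError):
    """An argument or simulation parameter violates its documented constraint.

    The message names the offending field.
    """


class FormatError(InfradianError, ValueError):
    """A cycle-record file violates the CSV schema; names row and field."""


class InsufficientDataError(InfradianError, ValueError):
    """A series or cohort is too short/small for the requested computation."""


class ConsistencyError(InfradianError, ValueError):
    """Objects passed together do not belong to the same series/cohort."""


class DataError(InfradianError, ValueError):
    """A record is missing information required by the analysis."""
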