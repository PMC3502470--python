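"""Exception hierarchy shared across the package."""


class MsqError(Exception):
    """Base class for all package errors."""


class DefinitionError(MsqError):
    """An instrument or crosswalk document is malformed."""


class StructuralError(DefinitionError):
    """Item counts or subscale cardinalities do not match the instrument."""


class ResponseError(MsqError):
    """A respondent record references unknown items or is untyped."""


class RangeError(MsqError, ValueError):
    """A numeric argument lies outside its documented bounds."""


class ScoringError(MsqError):
    """A score cannot be computed (e.g. missing answers under strict policy)."""


class CrosswalkError(MsqError):
    """The crosswalk does not cover a required target component."""


class ConfigError(MsqError):
    """Simulator or run configuration is invalid."""


class FormatError(MsqError):
    """A tabular input file has a malformed header or dialect."""


class AlignmentError(MsqError):
    """Original and calculated series do not share respondent ids."""


class StatsError(MsqError):
    """A statistic is undefined for the given input."""


class DegenerateFitError(StatsError):
    """Regression on a constant predictor."""
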