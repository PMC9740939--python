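"""Exception hierarchy shared across the pipeline stages."""


class HerbipkError(Exception):
    """Base class for all package errors."""


# --- concentration-time / NCA ---------------------------------------------

class NoQuantifiableDataError(HerbipkError):
    """Every observation in a profile is below the limit of quantification."""


class InsufficientDataError(HerbipkError):
    """Too few usable points for the requested computation."""


class TerminalPhaseError(HerbipkError):
    """No candidate terminal window yields a positive elimination rate."""


class InvalidDoseError(HerbipkError):
    """Dose is missing or non-positive where a dose-scaled parameter is needed."""


# --- integration -----------------------------------------------------------

class InvalidAUCError(HerbipkError):
    """An AUC needed for weighting is missing or non-positive."""


class GridAlignmentError(HerbipkError):
    """Profiles to be integrated do not share the same nominal time grid."""


class WeightCoverageError(HerbipkError):
    """Weight vector does not cover exactly the supplied analytes."""


# --- bioanalytical validation ---------------------------------------------

class RankDeficientError(HerbipkError):
    """Calibration design has no spread in x; the line is not identifiable."""


class UndefinedPrecisionError(HerbipkError):
    """Mean of replicate measurements is non-positive; RSD undefined."""


class InvalidReferenceError(HerbipkError):
    """A reference mean (post-spiked or neat) is zero or negative."""


class InvalidNoiseError(HerbipkError):
    """Baseline noise must be positive for a signal-to-noise ratio."""


# --- network pharmacology --------------------------------------------------

class EmptySetError(HerbipkError):
    """A target set that must be non-empty is empty."""


class UniverseViolationError(HerbipkError):
    """Query identifiers fall outside the enrichment universe."""


class InvalidPValueError(HerbipkError):
    """A p-value outside (0, 1] was passed to multiplicity adjustment."""


# --- configuration / IO ----------------------------------------------------

class ConfigurationError(HerbipkError):
    """A simulation or pipeline configuration field is invalid."""


class SchemaError(HerbipkError):
    """An input table is missing a required column."""


class ParseError(HerbipkError):
    """A cell could not be parsed; message carries the 1-based line number."""


class DuplicateRecordError(HerbipkError):
    """Duplicate (subject, analyte, time) rows in a concentration table."""
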