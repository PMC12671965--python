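"""Exception taxonomy shared across the pipeline."""


class EmutrialError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EmutrialError):
    """A scenario or analysis configuration value is invalid."""


class SchemaError(EmutrialError):
    """An input table is missing required columns or has wrong types."""


class DataError(EmutrialError):
    """Input records violate an internal consistency requirement
    (e.g. a death date before baseline)."""


class FitError(EmutrialError):
    """A model fit failed to converge or produced non-finite estimates."""


class SeparationError(FitError):
    """A logistic fit exhibits (quasi-)complete separation: fitted
    probabilities of 0 or 1 to machine precision, i.e. non-overlap."""
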