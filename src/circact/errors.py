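"""Exception hierarchy for the actigraphy pipeline."""


class CircactError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CircactError):
    """A file does not conform to the expected dialect (missing columns, bad header)."""


class DataError(CircactError):
    """A file parsed, but its contents violate the data model (bad timestamps, negative counts)."""


class ModelError(CircactError):
    """A statistical model could not be fitted on the supplied data."""


class SpecError(CircactError):
    """A simulation specification is internally inconsistent or infeasible."""
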