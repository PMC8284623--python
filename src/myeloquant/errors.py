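"""Exception types shared across the pipeline."""


class MyeloquantError(Exception):
    """Base class for all package errors."""


class ValidationError(MyeloquantError, ValueError):
    """A precondition on user-supplied parameters failed."""


class SchemaError(MyeloquantError, KeyError):
    """A required marker / column is missing from a table or image."""


class IntegrityError(MyeloquantError):
    """Rows or labels that must correspond do not (duplicates, coverage gaps)."""


class PlacementError(MyeloquantError):
    """Requested cell count could not be placed within the overlap budget."""


class InsufficientDataError(MyeloquantError):
    """A statistical operation was asked to run on too little data."""


class DegenerateSplitError(MyeloquantError):
    """A median split was requested on a constant metric."""


class ConfigError(MyeloquantError):
    """A rule or option refers to something that does not exist."""
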