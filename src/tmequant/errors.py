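"""Exception hierarchy shared across the package."""


class TmequantError(Exception):
    """Base class for all package errors."""


class SchemaError(TmequantError):
    """A required column or field is missing from an input table."""


class ValidationError(TmequantError):
    """An input violates a declared invariant (bad value, duplicate id, ...)."""


class FormatError(TmequantError):
    """Files that should agree in shape or content do not."""


class CapacityError(TmequantError):
    """Requested planted structures do not fit into the simulated region."""


class ParameterError(TmequantError):
    """A function parameter is outside its admissible range."""
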