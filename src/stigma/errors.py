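"""Exception taxonomy shared across the package."""


class StigmaError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(StigmaError):
    """Shapes of two inputs that must agree do not."""


class SchemaError(StigmaError):
    """A required column / feature is missing or mismatched."""


class EmptyResultError(StigmaError):
    """A filter removed everything."""


class ConfigurationError(StigmaError):
    """Inputs are structurally valid but unusable for the requested operation."""


class CoordinateError(StigmaError):
    """A genomic coordinate falls outside its chromosome."""
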