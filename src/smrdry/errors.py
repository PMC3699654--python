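"""Exception hierarchy.

``SchemaError`` signals malformed input tables (CLI exit code 2);
``DegenerateInputError`` signals numerically degenerate physics inputs such
as equal fluid densities (CLI exit code 3).
"""


class SmrDryError(ValueError):
    """Base class for all package-specific errors."""


class SchemaError(SmrDryError):
    """An input table violates its declared schema (names the row/column)."""


class DegenerateInputError(SmrDryError):
    """Inputs make the requested inversion or fit ill-posed."""


class MatchedDensityError(DegenerateInputError):
    """Fluid densities that must match (water-content mode) do not."""
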