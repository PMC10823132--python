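"""Exception hierarchy shared across the package."""


class RiverkillError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(RiverkillError):
    """River geometry violates its invariants (e.g. non-positive span)."""


class InvalidDetectionError(RiverkillError):
    """Detection rate outside (0, 1]."""


class InsufficientDataError(RiverkillError):
    """Too few observations for the requested estimator."""


class UnknownTaxonError(RiverkillError):
    """A taxon has no matching coefficient or record."""


class UndefinedRatioError(RiverkillError):
    """Reference taxon mean count is zero; the ratio is undefined."""


class SchemaError(RiverkillError):
    """Input table does not match the expected schema."""
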