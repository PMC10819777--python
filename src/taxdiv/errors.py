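"""Exception hierarchy shared across the package."""


class TaxdivError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TaxdivError):
    """Malformed input file (wrong delimiter count, bad numeric field, ...)."""


class LookupError_(TaxdivError):
    """A requested identifier does not exist in the queried structure."""


class ValidationError(TaxdivError):
    """An input violates a structural invariant (duplicate ids, cycles, ...)."""
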