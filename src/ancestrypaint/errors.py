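"""Exception hierarchy shared by every pipeline stage."""


class AncestryPaintError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(AncestryPaintError):
    """A file does not conform to the expected dialect (structure, headers)."""


class ValidationError(AncestryPaintError):
    """Well-formed input whose values violate a documented invariant."""
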