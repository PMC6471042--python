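"""Exception types used across the package."""


class ReplitimeError(Exception):
    """Base class for all replitime errors."""


class FormatError(ReplitimeError):
    """An input file violates its declared format."""


class CoordinateError(ReplitimeError):
    """A genomic coordinate falls outside the declared layout."""
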