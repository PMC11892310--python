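"""Shared exception types."""


class InsufficientDataError(ValueError):
    """An operation received fewer observations than it can support."""


class FormatError(ValueError):
    """An input file or table violates its format contract."""
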