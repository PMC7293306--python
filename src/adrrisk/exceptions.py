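"""Exception and warning types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented contract (range, shape, vocabulary)."""


class FormatError(ValidationError):
    """Raised when an input file does not match the expected tabular dialect."""


class UnknownDrugWarning(UserWarning):
    """Emitted when a queried drug is absent from the loaded knowledge base.

    Unknown drugs contribute nothing to the candidate ADR profile; warning
    instead of failing keeps partial knowledge bases usable.
    """
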