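"""Exception types used across the package."""


class ValidationError(ValueError):
    """An input object violates a documented invariant or precondition."""
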