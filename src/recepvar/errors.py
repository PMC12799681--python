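"""Exception types shared across the package."""


class ContractError(ValueError):
    """An input violates a documented precondition (shapes, atlases, masks)."""


class FormatError(ValueError):
    """A file on disk does not conform to the expected format."""
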