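"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid configuration: missing column, bad criteria, degenerate simulation setup."""


class ContractError(ValueError):
    """A documented precondition of an operation was violated by the caller."""
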