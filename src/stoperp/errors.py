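"""Exception types shared across the package."""


class StopErpError(ValueError):
    """Base class for all package-specific errors."""


class ConfigurationError(StopErpError):
    """A configuration object violates one of its invariants."""


class ContractError(StopErpError):
    """An operation was called with arguments outside its contract."""


class AnalysisError(StopErpError):
    """A quantity is undefined for the given data (e.g. empty scope)."""
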