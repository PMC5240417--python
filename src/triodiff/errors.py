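"""Exception types shared across the pipeline."""


class TriodiffError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TriodiffError, ValueError):
    """A configuration object violates one of its invariants."""


class InputError(TriodiffError, ValueError):
    """Malformed or inconsistent input data."""
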