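"""Exception types shared across the package."""


class ICModelsError(Exception):
    """Base class for all package-specific errors."""


class DataError(ICModelsError):
    """Malformed, empty, or inconsistent input data."""


class StateError(ICModelsError):
    """Sampler bookkeeping violated an invariant (internal bug guard)."""
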