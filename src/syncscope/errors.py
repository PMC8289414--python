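"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A simulation or run configuration is invalid."""


class InputError(ValueError):
    """An input array, table or parameter violates a precondition."""


class UndefinedResultError(RuntimeError):
    """A requested quantity is undefined for the given data (e.g. a fraction
    with an empty denominator)."""


class NoArrivalError(RuntimeError):
    """No bolus-arrival frame could be detected in a perfusion movie."""
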