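"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration field is missing or outside its valid range."""


class TraceFormatError(ValueError):
    """A trace table violates the expected CSV layout or time base."""


class ProtocolError(ValueError):
    """A required protocol annotation (stimulus, CPA, re-addition) is absent."""


class InsufficientDataError(ValueError):
    """A trace is too short for the requested analysis window."""
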