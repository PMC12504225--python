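"""Exception types shared across the package, mapped to CLI exit codes."""


class InvalidArgumentError(ValueError):
    """A caller-supplied argument is out of range or inconsistent (exit 2)."""


class SchemaError(ValueError):
    """Data does not match the expected channel/shape schema (exit 3)."""


class IncompleteResultError(RuntimeError):
    """A multi-part result is missing a required arm or cell (exit 4)."""
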