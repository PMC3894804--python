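"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A parameter or data structure violates a documented invariant."""


class CorruptFileError(IOError):
    """Header and payload of a session file disagree."""


class UnsupportedFormatError(IOError):
    """File declares a format version this package cannot read."""


class SpikeTableParseError(ValueError):
    """A spike/interval table contains an unparseable line."""

    def __init__(self, path, line_number, line):
        self.path = str(path)
        self.line_number = line_number
        self.line = line
        super().__init__(
            f"{self.path}:{line_number}: cannot parse {line!r} as a number"
        )


class WrongProtocolError(ValidationError):
    """An analysis was applied to a schedule of the wrong protocol kind."""
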