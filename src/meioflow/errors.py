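"""Exception types shared across the pipeline stages."""


class MeioflowError(Exception):
    """Base class for all package errors."""


class FormatError(MeioflowError):
    """A file is structurally unreadable (truncated, malformed segment)."""


class UnsupportedVersionError(FormatError):
    """An FCS file declares a version other than 3.0/3.1."""


class ParseError(MeioflowError):
    """A text table could not be parsed into numeric events."""


class MissingChannelError(MeioflowError, KeyError):
    """A required channel is absent from an event table."""

    def __init__(self, channel: str):
        super().__init__(f"required channel {channel!r} is not present")
        self.channel = channel


class ConvergenceError(MeioflowError):
    """The optimizer failed to converge from every starting point."""
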