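"""Exception hierarchy shared across the package."""


class ForumLensError(Exception):
    """Base class for all package errors."""


class ParseError(ForumLensError):
    """A record or file could not be parsed; message names the location."""


class ValidationError(ForumLensError):
    """Input violated a documented precondition or invariant."""
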