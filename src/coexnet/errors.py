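"""Exception hierarchy.

``InputError`` marks problems a user can fix (malformed files, bad config
values); anything else escaping the library is treated as an internal error
by the CLI (exit code 2).
"""


class CoexnetError(Exception):
    """Base class for all errors raised by coexnet."""


class InputError(CoexnetError):
    """Malformed input data or invalid user-supplied parameters."""
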