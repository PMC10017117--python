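"""Exception hierarchy.

``ValidationError`` covers everything a user can fix by fixing their input
(garbled files, missing dates, mismatched labels); anything else escaping the
library is an internal bug. The CLI maps ValidationError to exit code 2.
"""


class TemposcanError(Exception):
    """Base class for all temposcan errors."""


class ValidationError(TemposcanError):
    """Invalid or inconsistent user input."""


class TreeParseError(ValidationError):
    """The tree file could not be parsed in the declared dialect."""
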