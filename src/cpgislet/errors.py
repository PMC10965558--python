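"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration errors -> 2,
input/parse errors -> 3, anything else raised during compute -> 4.
"""


class CpgIsletError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CpgIsletError):
    """Invalid parameter combination detected before any compute."""


class InputError(CpgIsletError):
    """Missing or unreadable input."""


class ParseError(InputError):
    """Malformed input file; message carries the offending line number."""


class ComputeError(CpgIsletError):
    """A stage failed during computation."""
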