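"""Exception hierarchy shared across the package.

Exit-code convention for the CLI: 0 ok, 2 input/format/parameter error,
3 convergence or numerical error.
"""


class PrognetError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(PrognetError):
    """Invalid or inconsistent input data."""

    exit_code = 2


class FormatError(InputError):
    """Malformed on-disk file."""


class ParameterError(InputError):
    """Invalid parameter value."""


class ConvergenceError(PrognetError):
    """Iterative procedure failed to converge."""

    exit_code = 3
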