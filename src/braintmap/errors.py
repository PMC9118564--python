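"""Exception hierarchy mapped onto CLI exit codes (2 = input, 3 = statistical)."""


class BraintmapError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(BraintmapError):
    """Malformed or inconsistent input data (file contents, labels, config)."""

    exit_code = 2


class StatisticalError(BraintmapError):
    """A statistical precondition failed (rank deficiency, too few subjects,
    no usable tests, invalid alpha)."""

    exit_code = 3
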