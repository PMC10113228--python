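"""Package exception hierarchy (mapped to CLI exit codes)."""


class DataError(ValueError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


class NumericError(RuntimeError):
    """Numerical failure: non-convergence or rank deficiency (exit code 4)."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []
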