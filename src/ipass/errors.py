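"""Exception hierarchy shared across the package."""


class IpassError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IpassError):
    """Malformed input file or table (bad values, missing fields, duplicates)."""


class ValidationError(IpassError):
    """A domain object violates one of its invariants."""


class DegenerateCalibrationError(IpassError):
    """Raised when cohort raw scores have no spread, so min-max scaling is undefined."""


class MissingGenesError(IpassError):
    """Signature or panel genes absent from an expression matrix."""

    def __init__(self, missing: list[str], context: str = "matrix"):
        self.missing = sorted(missing)
        super().__init__(
            f"{len(self.missing)} gene(s) missing from {context}: "
            + ", ".join(self.missing[:10])
            + ("..." if len(self.missing) > 10 else "")
        )
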