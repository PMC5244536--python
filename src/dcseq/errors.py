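"""Exception types raised across the package."""


class DcseqError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DcseqError):
    """A file violates the expected table layout (duplicate ids, bad shape)."""


class ParseError(DcseqError):
    """A cell could not be parsed as a number; message names the cell."""


class ValidationError(DcseqError):
    """Input values violate a documented precondition."""


class EmptyResultError(DcseqError):
    """An operation removed every record (e.g. all features flagged)."""


class SingularSystemError(DcseqError):
    """A linear system required by an estimator is singular."""


class ConvergenceError(DcseqError):
    """Too many EM subsampling rounds failed to converge."""
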