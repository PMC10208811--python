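"""Exception hierarchy for the bmrscale pipeline.

Validation problems (bad tables, bad trees) and numerical problems
(singular designs, non-finite likelihoods) are kept distinct so the CLI
can map them to different exit codes.
"""


class BmrScaleError(Exception):
    """Base class for all bmrscale errors."""


class FormatError(BmrScaleError):
    """An input file does not have the expected structure (e.g. a missing column)."""


class DataValidationError(BmrScaleError):
    """Input parsed, but violates a domain invariant (duplicates, out-of-range values)."""


class InsufficientDataError(DataValidationError):
    """Too few observations or groups for the requested fit."""


class SingularDesignError(BmrScaleError):
    """The regression design matrix is rank-deficient (e.g. constant predictor)."""


class NumericalError(BmrScaleError):
    """A numerical operation failed (singular covariance, non-finite likelihood)."""
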