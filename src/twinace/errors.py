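"""Exception types shared across the package."""


class TwinAceError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TwinAceError, ValueError):
    """Input violates a structural invariant (bad proportions, bad pairing, ...)."""


class CohortFormatError(TwinAceError, ValueError):
    """A cohort file does not conform to the expected CSV dialect."""


class DegenerateDataError(TwinAceError, ValueError):
    """Data carry no usable variation (constant trait, empty contingency row, ...)."""


class InsufficientDataError(TwinAceError, ValueError):
    """Too few complete pairs or subjects for the requested computation."""
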