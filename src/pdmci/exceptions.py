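"""Exception hierarchy shared across the package."""


class PdmciError(Exception):
    """Base class for all package errors."""


class ValidationError(PdmciError, ValueError):
    """Raised when an input violates a documented contract."""


class DegenerateDesignError(PdmciError, ValueError):
    """Raised when a statistical design cannot be estimated.

    Typical causes: a group with fewer subjects than covariates + 1,
    an empty permutation family, or an undefined correlation
    (constant variable).
    """
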