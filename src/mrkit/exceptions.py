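"""Exception hierarchy.

Everything raised deliberately by mrkit derives from :class:`MRKitError` so
callers (and the CLI) can distinguish analysis failures from programming bugs.
"""


class MRKitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MRKitError):
    """A user-supplied configuration is invalid (bad column map, bad scenario
    parameters, variance budget exceeded, ...)."""


class ValidationError(MRKitError):
    """Input data violate a structural invariant (duplicate SNP ids, empty
    table, ...). Per-row invariant failures are *rejected and logged*, not
    raised; this error is for table-level problems."""


class HarmonizationError(MRKitError):
    """Harmonization cannot proceed for a named SNP (e.g. missing EAF on a
    palindromic SNP under the ``infer_by_eaf`` policy)."""


class LDMissingError(MRKitError):
    """An LD value required by clumping (pair within the window) is absent
    from the supplied LD information."""


class DegenerateDesignError(MRKitError):
    """All exposure effects are zero: the IVW regression through the origin
    is undefined."""


class RankDeficiencyError(MRKitError):
    """The multivariable design is (numerically) collinear."""

    def __init__(self, message: str, condition_number: float | None = None):
        super().__init__(message)
        self.condition_number = condition_number


class InsufficientDataError(MRKitError):
    """Too few SNPs for the requested estimator or diagnostic."""


class ScaleMisuseError(MRKitError):
    """An odds-scale conversion was requested for a continuous outcome."""
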