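"""Exception hierarchy.

Every failure mode promised by the public API maps onto one of these, so
callers can distinguish bad input from numerical breakdown.
"""


class IslePrsError(Exception):
    """Base class for all package-specific errors."""


class CaseCountUnreachable(IslePrsError):
    """Rejection sampling hit its iteration cap before filling the case quota."""


class MissingSnpError(IslePrsError):
    """A panel SNP is absent from the supplied dosage matrix."""


class AlleleMismatchError(IslePrsError):
    """Effect-table alleles cannot be reconciled with the dosage alleles."""


class PalindromicSnpError(AlleleMismatchError):
    """Strand-ambiguous (A/T or C/G) SNP rejected at harmonisation."""


class DegenerateInputError(IslePrsError):
    """Input lacks the variation the requested statistic needs."""


class CollinearityError(DegenerateInputError):
    """Singular model design matrix; names the offending columns."""


class ConvergenceFailure(IslePrsError):
    """Iterative fit did not converge within the iteration budget."""


class SeparationError(ConvergenceFailure):
    """(Quasi-)complete separation: the logistic MLE diverges."""
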