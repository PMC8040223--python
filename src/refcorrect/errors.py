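"""Typed errors raised across the package.

Zero denominators signal an invalid study configuration, not an
estimable-but-out-of-range result, so they raise rather than flag.
"""


class EstimationError(ValueError):
    """Base class for errors raised while applying an estimator."""


class DegenerateMarginError(EstimationError):
    """A required margin of the 2x2 table is zero.

    ``margin`` identifies the offending margin ("e" for reference-positive,
    "f" for reference-negative).
    """

    def __init__(self, margin: str, message: str | None = None):
        self.margin = margin
        super().__init__(message or f"degenerate table margin: {margin} = 0")


class DegenerateReferenceError(EstimationError):
    """A correction denominator built from the reference accuracy is zero.

    ``quantity`` names the vanishing expression.
    """

    def __init__(self, quantity: str, message: str | None = None):
        self.quantity = quantity
        super().__init__(message or f"degenerate correction denominator: {quantity} = 0")


class UninformativeReferenceError(EstimationError):
    """Youden's index of the reference standard is zero (Sn + Sp = 1)."""

    def __init__(self, message: str | None = None):
        super().__init__(
            message
            or "reference standard is uninformative: Youden's index J = Sn + Sp - 1 = 0"
        )


class DegenerateInputError(EstimationError):
    """A denominator of the count-form corrected estimator is not positive."""

    def __init__(self, quantity: str, message: str | None = None):
        self.quantity = quantity
        super().__init__(message or f"degenerate denominator: {quantity} <= 0")


class InfeasibleCovarianceError(ValueError):
    """Covariance terms violate the cell-probability feasibility bounds."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "infeasible covariance terms: " + "; ".join(self.violations)
        )


class EmptySummaryError(RuntimeError):
    """Every replicate was undefined for a method; no summary can be formed."""

    def __init__(self, method: str, reason: str = "all replicates undefined"):
        self.method = method
        super().__init__(f"empty summary for method {method!r}: {reason}")


class UnknownCaseStudyError(KeyError):
    """Requested case-study id does not exist."""

    def __init__(self, case_id: str, valid: tuple[str, ...]):
        self.case_id = case_id
        self.valid = valid
        super().__init__(
            f"unknown case study {case_id!r}; valid ids: {', '.join(valid)}"
        )
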