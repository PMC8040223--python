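"""Closed-form accuracy estimators for a binary index test.

Implements the classical (gold-standard) estimates and three algebraic
correction methods that adjust the index test's sensitivity and specificity
for a reference standard whose own sensitivity and specificity are known
but imperfect: the Staquet estimators, the Gart-Buck estimators (algebraically
equivalent to Staquet), and the Brenner estimators.  Wilson score intervals
are provided for uncertainty quantification.

Notation: the 2x2 table has cells a, b, c, d with margins e = a+c (RS+),
f = b+d (RS-), g = a+b (IT+), h = c+d (IT-), total N, sample prevalence
Prr = e/N, and the reference standard has Youden's index J = Sn_RS + Sp_RS - 1.
"""

from __future__ import annotations

import math
from dataclasses import replace

from scipy.stats import norm

from .errors import (
    DegenerateInputError,
    DegenerateMarginError,
    DegenerateReferenceError,
    UninformativeReferenceError,
)
from .types import AccuracyEstimate, ContingencyTable, CorrectionResult, ReferenceAccuracy

__all__ = [
    "classical_estimate",
    "staquet_correct",
    "staquet_prevalence",
    "gart_buck_correct",
    "brenner_correct",
    "brenner_probability_form",
    "wilson_interval",
    "attach_wilson_ci",
    "ESTIMATOR_NAMES",
]

ESTIMATOR_NAMES = ("classical", "brenner", "staquet", "gart_buck")

# relative tolerance used to detect vanishing correction denominators
_DEGENERATE_RTOL = 1e-12


def classical_estimate(table: ContingencyTable) -> CorrectionResult:
    """Uncorrected estimates, treating the reference standard as a gold standard.

    Sn = a/e, Sp = d/f, sample prevalence Prr = e/N.  These estimates are
    proportions of observed counts, so they are never illogical.

    Raises
    ------
    DegenerateMarginError
        If the RS-positive margin ``e`` or RS-negative margin ``f`` is zero.
    """
    if table.e == 0:
        raise DegenerateMarginError("e", "no reference-positive participants (e = a + c = 0)")
    if table.f == 0:
        raise DegenerateMarginError("f", "no reference-negative participants (f = b + d = 0)")
    return CorrectionResult(
        method="classical",
        sensitivity=AccuracyEstimate.of(table.a / table.e),
        specificity=AccuracyEstimate.of(table.d / table.f),
        sample_prevalence=table.sample_prevalence,
    )


def _require_informative(ref: ReferenceAccuracy) -> None:
    if ref.j == 0:
        raise UninformativeReferenceError()


def _check_denominator(value: float, scale: float, quantity: str) -> None:
    if abs(value) <= _DEGENERATE_RTOL * scale:
        raise DegenerateReferenceError(quantity)


def staquet_prevalence(table: ContingencyTable, ref: ReferenceAccuracy) -> AccuracyEstimate:
    """Misclassification-corrected prevalence.

    P-hat = (N (Sp_RS - 1) + e) / (N J).  This is the Rogan-Gladen form:
    the observed RS-positive rate shifted by the false-positive rate and
    rescaled by Youden's index.  The raw value may fall outside [0, 1];
    it is flagged, not clamped.
    """
    _require_informative(ref)
    return AccuracyEstimate.of(
        (table.n * (ref.sp - 1.0) + table.e) / (table.n * ref.j)
    )


def staquet_correct(table: ContingencyTable, ref: ReferenceAccuracy) -> CorrectionResult:
    """Staquet-corrected sensitivity and specificity (conditional independence).

    Sn = (g Sp_RS - b) / (N (Sp_RS - 1) + e)
    Sp = (h Sn_RS - c) / (N Sn_RS - e)

    together with the corrected prevalence from :func:`staquet_prevalence`.
    Estimates outside [0, 1] are flagged as illogical.

    Raises
    ------
    UninformativeReferenceError
        If Youden's index of the reference standard is zero.
    DegenerateReferenceError
        If either correction denominator vanishes.
    """
    _require_informative(ref)
    den_sn = table.n * (ref.sp - 1.0) + table.e
    den_sp = table.n * ref.sn - table.e
    _check_denominator(den_sn, table.n, "N(Sp_RS - 1) + e")
    _check_denominator(den_sp, table.n, "N Sn_RS - e")
    return CorrectionResult(
        method="staquet",
        sensitivity=AccuracyEstimate.of((table.g * ref.sp - table.b) / den_sn),
        specificity=AccuracyEstimate.of((table.h * ref.sn - table.c) / den_sp),
        sample_prevalence=table.sample_prevalence,
        prevalence=staquet_prevalence(table, ref),
    )


def gart_buck_correct(table: ContingencyTable, ref: ReferenceAccuracy) -> CorrectionResult:
    """Gart-Buck corrected sensitivity and specificity.

    Written in terms of the classical estimates (Sn_IT, Sp_IT, Prr) and the
    corrected prevalence P-hat:

    Sn = [Sp_RS Prr Sn_IT + (1 - Sp_RS)(1 - Prr) Sp_IT
          - (1 - Sp_RS)(Sp_RS - P-hat J)] / (P-hat J)
    Sp = [Sn_RS (1 - Prr) Sp_IT + (1 - Sn_RS) Prr Sn_IT
          - (1 - Sn_RS)(1 - Sp_RS + P-hat J)] / (J (1 - P-hat))

    Algebraically identical to :func:`staquet_correct`; kept as a distinct
    code path so the equivalence can be verified rather than assumed.
    """
    _require_informative(ref)
    cls = classical_estimate(table)
    prr = cls.sample_prevalence
    sn_it, sp_it = cls.sensitivity.value, cls.specificity.value
    p_hat = staquet_prevalence(table, ref).value
    j = ref.j
    # P-hat * J = (N(Sp_RS - 1) + e)/N and J(1 - P-hat) = (N Sn_RS - e)/N
    _check_denominator(p_hat * j, 1.0, "P-hat * J")
    _check_denominator(j * (1.0 - p_hat), 1.0, "J (1 - P-hat)")
    sn = (
        ref.sp * prr * sn_it
        + (1.0 - ref.sp) * (1.0 - prr) * sp_it
        - (1.0 - ref.sp) * (ref.sp - p_hat * j)
    ) / (p_hat * j)
    sp = (
        ref.sn * (1.0 - prr) * sp_it
        + (1.0 - ref.sn) * prr * sn_it
        - (1.0 - ref.sn) * (1.0 - ref.sp + p_hat * j)
    ) / (j * (1.0 - p_hat))
    return CorrectionResult(
        method="gart_buck",
        sensitivity=AccuracyEstimate.of(sn),
        specificity=AccuracyEstimate.of(sp),
        sample_prevalence=prr,
    )


def brenner_probability_form(
    prr: float, sn_it: float, sp_it: float, ref: ReferenceAccuracy
) -> tuple[float, float]:
    """Brenner estimators parameterised by (Prr, Sn_IT, Sp_IT).

    Sn = [Prr Sn_RS Sn_IT + (1 - Prr)(1 - Sp_RS)(1 - Sp_IT)]
         / [Prr Sn_RS + (1 - Prr)(1 - Sp_RS)]
    Sp = [Prr (1 - Sn_RS)(1 - Sn_IT) + (1 - Prr) Sp_RS Sp_IT]
         / [Prr (1 - Sn_RS) + (1 - Prr) Sp_RS]
    """
    den_sn = prr * ref.sn + (1.0 - prr) * (1.0 - ref.sp)
    den_sp = prr * (1.0 - ref.sn) + (1.0 - prr) * ref.sp
    if den_sn <= 0:
        raise DegenerateInputError("Prr Sn_RS + (1 - Prr)(1 - Sp_RS)")
    if den_sp <= 0:
        raise DegenerateInputError("Prr (1 - Sn_RS) + (1 - Prr) Sp_RS")
    sn = (prr * ref.sn * sn_it + (1.0 - prr) * (1.0 - ref.sp) * (1.0 - sp_it)) / den_sn
    sp = (prr * (1.0 - ref.sn) * (1.0 - sn_it) + (1.0 - prr) * ref.sp * sp_it) / den_sp
    return sn, sp


def brenner_correct(table: ContingencyTable, ref: ReferenceAccuracy) -> CorrectionResult:
    """Brenner-corrected sensitivity and specificity (count form).

    Sn = (a Sn_RS + b (1 - Sp_RS)) / (e Sn_RS + f (1 - Sp_RS))
    Sp = (c (1 - Sn_RS) + d Sp_RS) / (e (1 - Sn_RS) + f Sp_RS)

    Both estimates are weighted averages of observed proportions, so they
    always lie in [0, 1].  When both margins are positive the equivalent
    prevalence-parameterised form is evaluated as an internal cross-check.

    Raises
    ------
    DegenerateInputError
        If either denominator is not strictly positive.
    """
    den_sn = table.e * ref.sn + table.f * (1.0 - ref.sp)
    den_sp = table.e * (1.0 - ref.sn) + table.f * ref.sp
    if den_sn <= 0:
        raise DegenerateInputError("e Sn_RS + f (1 - Sp_RS)")
    if den_sp <= 0:
        raise DegenerateInputError("e (1 - Sn_RS) + f Sp_RS")
    sn = (table.a * ref.sn + table.b * (1.0 - ref.sp)) / den_sn
    sp = (table.c * (1.0 - ref.sn) + table.d * ref.sp) / den_sp
    if table.e > 0 and table.f > 0:
        cls = classical_estimate(table)
        sn_alt, sp_alt = brenner_probability_form(
            cls.sample_prevalence, cls.sensitivity.value, cls.specificity.value, ref
        )
        assert math.isclose(sn, sn_alt, rel_tol=1e-9, abs_tol=1e-12)
        assert math.isclose(sp, sp_alt, rel_tol=1e-9, abs_tol=1e-12)
    return CorrectionResult(
        method="brenner",
        sensitivity=AccuracyEstimate.of(sn),
        specificity=AccuracyEstimate.of(sp),
        sample_prevalence=table.sample_prevalence,
    )


def wilson_interval(
    point: float, n: float, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score confidence interval for a proportion.

    Centred at (point + z^2/2n) / (1 + z^2/n); both bounds lie in [0, 1].

    Raises
    ------
    ValueError
        If ``point`` lies outside [0, 1] (illogical estimates get no CI)
        or ``n`` < 1.
    """
    if not 0.0 <= point <= 1.0:
        raise ValueError(f"Wilson interval undefined for point {point} outside [0, 1]")
    if n < 1:
        raise ValueError(f"Wilson interval requires n >= 1, got {n}")
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must lie in (0, 1), got {confidence}")
    z = norm.ppf(1.0 - (1.0 - confidence) / 2.0)
    denom = 1.0 + z * z / n
    centre = (point + z * z / (2.0 * n)) / denom
    half = z * math.sqrt(point * (1.0 - point) / n + z * z / (4.0 * n * n)) / denom
    # at the boundaries the exact bound is the boundary itself
    lower = 0.0 if point == 0.0 else max(centre - half, 0.0)
    upper = 1.0 if point == 1.0 else min(centre + half, 1.0)
    return lower, upper


def attach_wilson_ci(
    result: CorrectionResult,
    table: ContingencyTable,
    confidence: float = 0.95,
    point_dp: int | None = None,
) -> CorrectionResult:
    """Return a copy of ``result`` with Wilson CIs on logical Sn/Sp estimates.

    Uses n = e for sensitivity and n = f for specificity.  ``point_dp``
    optionally rounds the point estimate before the interval is computed;
    the published clinical tables used 2-dp rounded points for the corrected
    methods (see :mod:`refcorrect.casestudies`).  Illogical estimates keep
    ``ci=None``.
    """

    def _ci(est: AccuracyEstimate, n: float) -> AccuracyEstimate:
        if est.illogical or n < 1:
            return est
        point = round(est.value, point_dp) if point_dp is not None else est.value
        return est.with_ci(wilson_interval(point, n, confidence))

    return replace(
        result,
        sensitivity=_ci(result.sensitivity, table.e),
        specificity=_ci(result.specificity, table.f),
    )
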