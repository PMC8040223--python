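"""Domain types: 2x2 tables, reference accuracy, and estimate containers."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

__all__ = [
    "ContingencyTable",
    "ReferenceAccuracy",
    "AccuracyEstimate",
    "CorrectionResult",
]


def _check_count(name: str, value: float) -> float:
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"cell count {name} must be finite and non-negative, got {value}")
    return value


@dataclass(frozen=True)
class ContingencyTable:
    """Observed 2x2 cross-classification of index test (IT) vs reference standard (RS).

    Cells follow the usual layout:

    ==========  =====  =====
    ..          RS+    RS-
    ==========  =====  =====
    IT+         a      b
    IT-         c      d
    ==========  =====  =====

    Counts are normally non-negative integers; non-negative reals are
    accepted so that expected-count (``N * p_ij``) tables can be analysed
    directly, e.g. for plug-in identity checks.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            _check_count(name, getattr(self, name))
        if self.n == 0:
            raise ValueError("table is empty: a + b + c + d must be positive")

    @property
    def e(self) -> float:
        """RS-positive margin, a + c."""
        return self.a + self.c

    @property
    def f(self) -> float:
        """RS-negative margin, b + d."""
        return self.b + self.d

    @property
    def g(self) -> float:
        """IT-positive margin, a + b."""
        return self.a + self.b

    @property
    def h(self) -> float:
        """IT-negative margin, c + d."""
        return self.c + self.d

    @property
    def n(self) -> float:
        """Total number of participants."""
        return self.a + self.b + self.c + self.d

    @property
    def sample_prevalence(self) -> float:
        """RS-positive fraction Prr = e / N."""
        return self.e / self.n

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    @classmethod
    def from_dict(cls, record: dict) -> "ContingencyTable":
        missing = [k for k in ("a", "b", "c", "d") if k not in record]
        if missing:
            raise ValueError(f"table record missing keys: {', '.join(missing)}")
        return cls(*(float(record[k]) for k in ("a", "b", "c", "d")))

    @classmethod
    def from_file(cls, path: str | Path) -> "ContingencyTable":
        """Read a table from a CSV file with header ``a,b,c,d`` or a JSON object."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
            return cls.from_dict(json.loads(text))
        import pandas as pd

        frame = pd.read_csv(path)
        if frame.empty:
            raise ValueError(f"no data rows in {path}")
        return cls.from_dict(frame.iloc[0].to_dict())


@dataclass(frozen=True)
class ReferenceAccuracy:
    """Known sensitivity and specificity of the imperfect reference standard."""

    sn: float
    sp: float

    def __post_init__(self) -> None:
        for name, value in (("sn", self.sn), ("sp", self.sp)):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"reference {name} must lie in [0, 1], got {value}")

    @property
    def j(self) -> float:
        """Youden's index, Sn + Sp - 1."""
        return self.sn + self.sp - 1.0

    @property
    def is_perfect(self) -> bool:
        return self.sn == 1.0 and self.sp == 1.0


@dataclass(frozen=True)
class AccuracyEstimate:
    """A point estimate that may fall outside [0, 1].

    ``value`` is never clamped.  ``illogical`` is True exactly when the value
    lies outside the unit interval, in which case no confidence interval is
    attached (published tables print "NaN" there).
    """

    value: float
    illogical: bool
    ci: Optional[tuple[float, float]] = None

    @classmethod
    def of(cls, value: float) -> "AccuracyEstimate":
        return cls(value=value, illogical=not (0.0 <= value <= 1.0))

    def with_ci(self, ci: Optional[tuple[float, float]]) -> "AccuracyEstimate":
        if self.illogical and ci is not None:
            raise ValueError("cannot attach a confidence interval to an illogical estimate")
        return replace(self, ci=ci)


@dataclass(frozen=True)
class CorrectionResult:
    """Per-method sensitivity/specificity estimates for one 2x2 table."""

    method: str
    sensitivity: AccuracyEstimate
    specificity: AccuracyEstimate
    sample_prevalence: float
    prevalence: Optional[AccuracyEstimate] = None

    def to_record(self) -> dict:
        """Flat record suitable for CSV/JSON output."""

        def _ci(est: AccuracyEstimate) -> tuple[Optional[float], Optional[float]]:
            return est.ci if est.ci is not None else (None, None)

        sn_lo, sn_hi = _ci(self.sensitivity)
        sp_lo, sp_hi = _ci(self.specificity)
        return {
            "method": self.method,
            "sn": self.sensitivity.value,
            "sn_lo": sn_lo,
            "sn_hi": sn_hi,
            "sn_illogical": self.sensitivity.illogical,
            "sp": self.specificity.value,
            "sp_lo": sp_lo,
            "sp_hi": sp_hi,
            "sp_illogical": self.specificity.illogical,
            "prevalence": self.prevalence.value if self.prevalence else None,
            "prevalence_illogical": self.prevalence.illogical if self.prevalence else None,
            "sample_prevalence": self.sample_prevalence,
        }
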