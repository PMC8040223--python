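"""Synthetic 2x2 tables from a fixed-effects dependence model.

Joint cell probabilities for (index test, reference standard) results are a
prevalence-weighted mixture of the two class-conditional 2x2 distributions.
Within each class the joint probability is the product of the marginal
positivity probabilities plus/minus a fixed covariance term (zero under
conditional independence).  Replicate tables are multinomial draws from the
four cell probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import InfeasibleCovarianceError
from .types import ContingencyTable

__all__ = [
    "ScenarioSpec",
    "JointCellProbabilities",
    "cell_probabilities",
    "validate_covariance_bounds",
    "covariance_bounds",
    "sample_tables",
    "predefined_scenarios",
    "DEFAULT_N_GRID",
]

# sample-size grid: 50 and 80 (discussed explicitly for small-sample
# behaviour), then 100..1000 in steps of 50
DEFAULT_N_GRID: tuple[int, ...] = (50, 80) + tuple(range(100, 1001, 50))


def _check_prob(name: str, value: float, open_interval: bool = False) -> None:
    lo_ok = value > 0.0 if open_interval else value >= 0.0
    hi_ok = value < 1.0 if open_interval else value <= 1.0
    if not (lo_ok and hi_ok):
        bounds = "(0, 1)" if open_interval else "[0, 1]"
        raise ValueError(f"{name} must lie in {bounds}, got {value}")


@dataclass(frozen=True)
class ScenarioSpec:
    """Generative truth for one simulation scenario.

    Parameters
    ----------
    prevalence : float
        Probability of the target condition, in (0, 1).
    sn_it, sp_it : float
        True sensitivity and specificity of the index test.
    sn_rs, sp_rs : float
        True sensitivity and specificity of the reference standard.
    cov_d, cov_nd : float
        Fixed covariance between the two tests' positive results within the
        diseased / non-diseased class; 0 gives conditional independence.
    n : int
        Participants per replicate table.
    reps : int
        Number of replicate tables.
    seed : int
        Root seed; replicates use spawned substreams so any prefix of the
        replicate sequence is reproducible.
    """

    prevalence: float
    sn_it: float
    sp_it: float
    sn_rs: float
    sp_rs: float
    cov_d: float = 0.0
    cov_nd: float = 0.0
    n: int = 1000
    reps: int = 200
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        _check_prob("prevalence", self.prevalence, open_interval=True)
        for attr in ("sn_it", "sp_it", "sn_rs", "sp_rs"):
            _check_prob(attr, getattr(self, attr))
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.reps < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")

    def with_(self, **changes) -> "ScenarioSpec":
        return replace(self, **changes)


@dataclass(frozen=True)
class JointCellProbabilities:
    """Joint probabilities of (IT, RS) outcomes: (+,+), (+,-), (-,+), (-,-)."""

    p11: float
    p10: float
    p01: float
    p00: float

    def __post_init__(self) -> None:
        for name in ("p11", "p10", "p01", "p00"):
            _check_prob(name, getattr(self, name))
        if abs(sum(self.as_array()) - 1.0) > 1e-12:
            raise ValueError("cell probabilities must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p11, self.p10, self.p01, self.p00])


def covariance_bounds(m1: float, m2: float) -> tuple[float, float]:
    """Feasible covariance range for two Bernoulli margins m1, m2.

    All four joint cell probabilities (m1 m2 + cov, m1(1-m2) - cov,
    (1-m1) m2 - cov, (1-m1)(1-m2) + cov) lie in [0, 1] iff

        max(-m1 m2, -(1-m1)(1-m2)) <= cov <= min(m1 (1-m2), (1-m1) m2)
    """
    lower = max(-m1 * m2, -(1.0 - m1) * (1.0 - m2))
    upper = min(m1 * (1.0 - m2), (1.0 - m1) * m2)
    return lower, upper


def validate_covariance_bounds(spec: ScenarioSpec) -> list[str]:
    """Return a list of violated feasibility bounds (empty when feasible)."""
    violations: list[str] = []
    for label, m1, m2, cov in (
        ("cov_d", spec.sn_it, spec.sn_rs, spec.cov_d),
        ("cov_nd", spec.sp_it, spec.sp_rs, spec.cov_nd),
    ):
        lower, upper = covariance_bounds(m1, m2)
        if cov < lower:
            violations.append(f"{label} = {cov:.6g} below lower bound {lower:.6g}")
        if cov > upper:
            violations.append(f"{label} = {cov:.6g} above upper bound {upper:.6g}")
    return violations


def cell_probabilities(spec: ScenarioSpec) -> JointCellProbabilities:
    """Joint cell probabilities implied by a scenario.

    With p the prevalence, the diseased class contributes cells built from
    (Sn_IT, Sn_RS, cov_d) and the non-diseased class from (Sp_IT, Sp_RS,
    cov_nd); a positive non-diseased result for either test is a false
    positive, so the class margins enter as (1 - Sp).

    Raises
    ------
    InfeasibleCovarianceError
        If the covariance terms violate the feasibility bounds.
    """
    violations = validate_covariance_bounds(spec)
    if violations:
        raise InfeasibleCovarianceError(violations)
    p = spec.prevalence
    q = 1.0 - p
    p11 = p * (spec.sn_it * spec.sn_rs + spec.cov_d) + q * (
        (1.0 - spec.sp_it) * (1.0 - spec.sp_rs) + spec.cov_nd
    )
    p10 = p * (spec.sn_it * (1.0 - spec.sn_rs) - spec.cov_d) + q * (
        (1.0 - spec.sp_it) * spec.sp_rs - spec.cov_nd
    )
    p01 = p * ((1.0 - spec.sn_it) * spec.sn_rs - spec.cov_d) + q * (
        spec.sp_it * (1.0 - spec.sp_rs) - spec.cov_nd
    )
    p00 = p * ((1.0 - spec.sn_it) * (1.0 - spec.sn_rs) + spec.cov_d) + q * (
        spec.sp_it * spec.sp_rs + spec.cov_nd
    )
    return JointCellProbabilities(p11, p10, p01, p00)


def sample_tables(
    spec: ScenarioSpec, seed_sequence: np.random.SeedSequence | None = None
) -> list[ContingencyTable]:
    """Draw ``spec.reps`` multinomial replicate tables of size ``spec.n``.

    Each replicate uses its own spawned substream of the root seed, so the
    r-th table is the same whether 10 or 200 replicates are requested.
    """
    probs = cell_probabilities(spec).as_array()
    root = seed_sequence if seed_sequence is not None else np.random.SeedSequence(spec.seed)
    tables = []
    for child in root.spawn(spec.reps):
        rng = np.random.default_rng(child)
        a, b, c, d = rng.multinomial(spec.n, probs)
        tables.append(ContingencyTable(int(a), int(b), int(c), int(d)))
    return tables


def tables_to_records(
    tables: Sequence[ContingencyTable], scenario: str = "", n: int | None = None
) -> list[dict]:
    """Long-format records (scenario, rep, n, a, b, c, d) for CSV export."""
    return [
        {
            "scenario": scenario,
            "rep": r,
            "n": int(t.n) if n is None else n,
            "a": t.a,
            "b": t.b,
            "c": t.c,
            "d": t.d,
        }
        for r, t in enumerate(tables)
    ]


def predefined_scenarios(seed: int = 0, n: int = 1000) -> dict[str, ScenarioSpec]:
    """The four study scenarios, each with 200 replicates.

    - scenario_one: reference standard better than index test
      (Sn_RS = Sp_RS = 0.9; Sn_IT = 0.8, Sp_IT = 0.7).
    - scenario_two: index test better than reference standard
      (Sn_IT = Sp_IT = 0.9; Sn_RS = 0.8, Sp_RS = 0.7).
    - scenario_three: both tests equal (all accuracies 0.9).
    - dependence: positively correlated tests (Sn_IT = Sp_IT = 0.8,
      Sn_RS = Sp_RS = 0.9, cov_d = cov_nd = 0.05).

    Prevalence is 0.3 throughout.
    """
    common = dict(prevalence=0.3, n=n, reps=200, seed=seed)
    return {
        "scenario_one": ScenarioSpec(
            sn_it=0.8, sp_it=0.7, sn_rs=0.9, sp_rs=0.9, name="scenario_one", **common
        ),
        "scenario_two": ScenarioSpec(
            sn_it=0.9, sp_it=0.9, sn_rs=0.8, sp_rs=0.7, name="scenario_two", **common
        ),
        "scenario_three": ScenarioSpec(
            sn_it=0.9, sp_it=0.9, sn_rs=0.9, sp_rs=0.9, name="scenario_three", **common
        ),
        "dependence": ScenarioSpec(
            sn_it=0.8, sp_it=0.8, sn_rs=0.9, sp_rs=0.9,
            cov_d=0.05, cov_nd=0.05, name="dependence", **common
        ),
    }
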