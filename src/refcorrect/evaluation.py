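"""Monte-Carlo performance evaluation of the correction estimators.

Aggregates per-replicate estimates into mean, empirical SE (standard
deviation of replicate estimates), bias and MSE against the generating
truth, over sample-size grids and prevalence sweeps.

Conventions
-----------
- Empirical SE uses the sample standard deviation (ddof=1).
- MSE is the mean squared deviation from truth, so the exact decomposition
  MSE = population variance (ddof=0) + bias^2 holds per stratum.
- Illogical estimates are included in the aggregates by default (set
  ``exclude_illogical=True`` to drop them) and always counted.
- Replicates where a method's denominator is degenerate are dropped for
  that method and counted in ``n_dropped``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import estimators
from .errors import EmptySummaryError, EstimationError
from .simulator import DEFAULT_N_GRID, ScenarioSpec, sample_tables
from .types import ContingencyTable, CorrectionResult, ReferenceAccuracy

__all__ = [
    "PerformanceSummary",
    "SweepResult",
    "evaluate_methods",
    "sample_size_sweep",
    "prevalence_sweep",
    "export_summary",
    "DEFAULT_METHODS",
    "DEFAULT_PREVALENCE_GRID",
]

logger = logging.getLogger(__name__)

_METHOD_FNS: dict[str, Callable[[ContingencyTable, ReferenceAccuracy], CorrectionResult]] = {
    "classical": lambda table, ref: estimators.classical_estimate(table),
    "brenner": estimators.brenner_correct,
    "staquet": estimators.staquet_correct,
    "gart_buck": estimators.gart_buck_correct,
}

DEFAULT_METHODS: tuple[str, ...] = ("classical", "brenner", "staquet", "gart_buck")

# endpoints 0 and 1 are degenerate multinomials and are excluded
DEFAULT_PREVALENCE_GRID: tuple[float, ...] = tuple(
    round(p, 2) for p in np.arange(0.01, 1.0, 0.01)
)

EXPORT_COLUMNS = (
    "scenario",
    "axis_value",
    "method",
    "measure",
    "mean",
    "emp_se",
    "bias",
    "mse",
    "n_illogical",
    "n_dropped",
)


@dataclass(frozen=True)
class PerformanceSummary:
    """Monte-Carlo summary for one (stratum, method, measure) combination."""

    scenario: str
    method: str
    measure: str  # "sensitivity" | "specificity"
    axis: str  # "n" | "prevalence"
    axis_value: float
    truth: float
    reps: int
    n_used: int
    n_illogical: int
    n_dropped: int
    mean: float
    emp_se: float  # NaN when fewer than 2 usable replicates
    bias: float
    mse: float


@dataclass(frozen=True)
class SweepResult:
    """Performance summaries over a strictly increasing grid."""

    axis: str
    summaries: tuple[PerformanceSummary, ...]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame([s.__dict__ for s in self.summaries])
        return frame[list(EXPORT_COLUMNS)]


def _summarise(
    values: np.ndarray,
    truth: float,
    *,
    scenario: str,
    method: str,
    measure: str,
    axis: str,
    axis_value: float,
    reps: int,
    n_dropped: int,
    exclude_illogical: bool,
) -> PerformanceSummary:
    illogical = (values < 0.0) | (values > 1.0)
    n_illogical = int(illogical.sum())
    used = values[~illogical] if exclude_illogical else values
    if used.size == 0:
        raise EmptySummaryError(method, f"no usable {measure} estimates in stratum")
    mean = float(np.mean(used))
    emp_se = float(np.std(used, ddof=1)) if used.size > 1 else float("nan")
    return PerformanceSummary(
        scenario=scenario,
        method=method,
        measure=measure,
        axis=axis,
        axis_value=axis_value,
        truth=truth,
        reps=reps,
        n_used=int(used.size),
        n_illogical=n_illogical,
        n_dropped=n_dropped,
        mean=mean,
        emp_se=emp_se,
        bias=mean - truth,
        mse=float(np.mean((used - truth) ** 2)),
    )


def evaluate_methods(
    tables: Sequence[ContingencyTable],
    ref: ReferenceAccuracy,
    truth: ScenarioSpec,
    *,
    methods: Sequence[str] = DEFAULT_METHODS,
    exclude_illogical: bool = False,
    scenario: str | None = None,
    axis: str = "n",
    axis_value: float | None = None,
) -> list[PerformanceSummary]:
    """Apply each estimator to every replicate table and aggregate.

    Truth for bias/MSE is always the generating ``truth.sn_it`` /
    ``truth.sp_it``, never a plug-in expectation.

    Raises
    ------
    EmptySummaryError
        If every replicate is undefined (or, with ``exclude_illogical``,
        illogical) for some method.
    """
    if not tables:
        raise ValueError("tables must be nonempty")
    if ref.j == 0:
        raise EstimationError("reference Youden's index must be nonzero")
    unknown = [m for m in methods if m not in _METHOD_FNS]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}; valid: {sorted(_METHOD_FNS)}")
    scenario = scenario if scenario is not None else truth.name
    axis_value = axis_value if axis_value is not None else float(truth.n)
    reps = len(tables)
    out: list[PerformanceSummary] = []
    for method in methods:
        fn = _METHOD_FNS[method]
        sn_vals: list[float] = []
        sp_vals: list[float] = []
        dropped = 0
        for r, table in enumerate(tables):
            try:
                result = fn(table, ref)
            except EstimationError as exc:
                dropped += 1
                logger.debug("dropped replicate %d for %s: %s", r, method, exc)
                continue
            sn_vals.append(result.sensitivity.value)
            sp_vals.append(result.specificity.value)
        if dropped == reps:
            raise EmptySummaryError(method)
        for measure, vals, truth_value in (
            ("sensitivity", sn_vals, truth.sn_it),
            ("specificity", sp_vals, truth.sp_it),
        ):
            summary = _summarise(
                np.asarray(vals, dtype=float),
                truth_value,
                scenario=scenario,
                method=method,
                measure=measure,
                axis=axis,
                axis_value=axis_value,
                reps=reps,
                n_dropped=dropped,
                exclude_illogical=exclude_illogical,
            )
            if summary.n_illogical or summary.n_dropped:
                logger.info(
                    "%s/%s at %s=%s: %d illogical, %d dropped of %d replicates",
                    method, measure, axis, axis_value,
                    summary.n_illogical, summary.n_dropped, reps,
                )
            out.append(summary)
    return out


def _check_grid(grid: Sequence[float], name: str) -> list[float]:
    grid = list(grid)
    if not grid:
        raise ValueError(f"{name} must be nonempty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError(f"{name} must be strictly increasing")
    return grid


def sample_size_sweep(
    spec: ScenarioSpec,
    ref: ReferenceAccuracy,
    n_grid: Sequence[int] = DEFAULT_N_GRID,
    *,
    methods: Sequence[str] = DEFAULT_METHODS,
    exclude_illogical: bool = False,
) -> SweepResult:
    """Run :func:`evaluate_methods` at each sample size of a grid.

    Each grid point draws ``spec.reps`` fresh replicate tables from an
    independent substream of ``spec.seed``.
    """
    grid = _check_grid(n_grid, "n_grid")
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(len(grid))
    summaries: list[PerformanceSummary] = []
    for n, child in zip(grid, children):
        tables = sample_tables(spec.with_(n=int(n)), seed_sequence=child)
        summaries.extend(
            evaluate_methods(
                tables, ref, spec,
                methods=methods, exclude_illogical=exclude_illogical,
                axis="n", axis_value=float(n),
            )
        )
    return SweepResult(axis="n", summaries=tuple(summaries))


def prevalence_sweep(
    base: ScenarioSpec,
    ref: ReferenceAccuracy,
    prevalences: Sequence[float] = DEFAULT_PREVALENCE_GRID,
    *,
    methods: Sequence[str] = DEFAULT_METHODS,
    exclude_illogical: bool = False,
) -> SweepResult:
    """Run :func:`evaluate_methods` at each prevalence of a grid, n fixed.

    Illogical-estimate counts per stratum are surfaced in the summaries,
    never masked; very low / very high prevalences are expected to produce
    some.
    """
    grid = _check_grid(prevalences, "prevalence grid")
    if any(not 0.0 < p < 1.0 for p in grid):
        raise ValueError("prevalence grid values must lie strictly in (0, 1)")
    root = np.random.SeedSequence(base.seed)
    children = root.spawn(len(grid))
    summaries: list[PerformanceSummary] = []
    for p, child in zip(grid, children):
        spec = base.with_(prevalence=float(p))
        tables = sample_tables(spec, seed_sequence=child)
        summaries.extend(
            evaluate_methods(
                tables, ref, spec,
                methods=methods, exclude_illogical=exclude_illogical,
                scenario=base.name,
                axis="prevalence", axis_value=float(p),
            )
        )
    return SweepResult(axis="prevalence", summaries=tuple(summaries))


def export_summary(result: SweepResult, destination: str | Path) -> Path:
    """Write a sweep as long-format CSV with a stable column order.

    Values are written at full precision (round-trippable through
    ``pd.read_csv``).
    """
    if not result.summaries:
        raise ValueError("cannot export an empty sweep result")
    destination = Path(destination)
    result.to_frame().to_csv(destination, index=False)
    return destination
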