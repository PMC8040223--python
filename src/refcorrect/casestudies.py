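"""Packaged clinical 2x2 datasets and their re-analysis.

Three published comparisons of an index test against an imperfect reference
standard with externally validated accuracy:

- ``mathews_hra``: high-resolution anoscopy (HRA) cytology vs punch biopsy
  for high-grade squamous intraepithelial lesions in HIV patients.
- ``matos_nc_*``: laser-fluorescence pen (LFpen) and fluorescence camera
  (FC) vs visual inspection for non-cavitated occlusal caries lesions in
  primary teeth (examiner 1).
- ``matos_d3_*``: the same devices vs visual inspection for dentine caries
  lesions.

Counts were digitised from the published tables; each fixture is validated
against the printed margin totals at load time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from . import estimators
from .errors import UnknownCaseStudyError
from .types import ContingencyTable, CorrectionResult, ReferenceAccuracy

__all__ = ["CaseStudy", "CASE_STUDY_IDS", "load_case_study", "analyze_case_study", "report_frame"]


@dataclass(frozen=True)
class CaseStudy:
    id: str
    description: str
    condition: str
    table: ContingencyTable
    ref: ReferenceAccuracy


# counts (a, b, c, d), reference (Sn, Sp), and the printed margin totals
# (e, f, N) used as a digitisation check
_FIXTURES: dict[str, dict] = {
    "mathews_hra": dict(
        counts=(40, 22, 22, 177),
        ref=(0.74, 0.91),
        totals=(62, 199, 261),
        description="HRA cytology vs punch biopsy",
        condition="high-grade squamous intraepithelial lesion",
    ),
    "matos_nc_lfpen": dict(
        counts=(241, 6, 110, 26),
        ref=(0.796, 0.799),
        totals=(351, 32, 383),
        description="LFpen vs visual inspection, examiner 1",
        condition="non-cavitated caries lesion",
    ),
    "matos_nc_fc": dict(
        counts=(156, 3, 195, 29),
        ref=(0.796, 0.799),
        totals=(351, 32, 383),
        description="Fluorescence camera vs visual inspection, examiner 1",
        condition="non-cavitated caries lesion",
    ),
    "matos_d3_lfpen": dict(
        counts=(20, 45, 1, 341),
        ref=(0.786, 0.995),
        totals=(21, 386, 407),
        description="LFpen vs visual inspection, examiner 1",
        condition="dentine caries lesion",
    ),
    "matos_d3_fc": dict(
        counts=(21, 38, 0, 348),
        ref=(0.786, 0.995),
        totals=(21, 386, 407),
        description="Fluorescence camera vs visual inspection, examiner 1",
        condition="dentine caries lesion",
    ),
}

CASE_STUDY_IDS: tuple[str, ...] = tuple(_FIXTURES)


def load_case_study(case_id: str) -> CaseStudy:
    """Return a packaged fixture, validated against its printed totals.

    Raises
    ------
    UnknownCaseStudyError
        If ``case_id`` is not one of :data:`CASE_STUDY_IDS`.
    """
    try:
        fx = _FIXTURES[case_id]
    except KeyError:
        raise UnknownCaseStudyError(case_id, CASE_STUDY_IDS) from None
    table = ContingencyTable(*fx["counts"])
    e, f, n = fx["totals"]
    if (table.e, table.f, table.n) != (e, f, n):
        raise AssertionError(
            f"fixture {case_id} margins {(table.e, table.f, table.n)} "
            f"disagree with printed totals {(e, f, n)}"
        )
    return CaseStudy(
        id=case_id,
        description=fx["description"],
        condition=fx["condition"],
        table=table,
        ref=ReferenceAccuracy(*fx["ref"]),
    )


_ANALYSIS_METHODS = {
    "classical": lambda t, ref: estimators.classical_estimate(t),
    "brenner": estimators.brenner_correct,
    "staquet": estimators.staquet_correct,
    "gart_buck": estimators.gart_buck_correct,
}


def analyze_case_study(
    cs: CaseStudy,
    methods: Sequence[str] = ("classical", "brenner", "staquet", "gart_buck"),
    confidence: float = 0.95,
    published_ci_convention: bool = True,
) -> dict[str, CorrectionResult]:
    """Run the requested estimators with Wilson CIs attached.

    CIs use n = e for sensitivity and n = f for specificity.  Under the
    published convention the corrected methods' intervals are computed from
    the 2-dp rounded point estimate (the classical intervals always come
    from the exact proportion); this reproduces the printed clinical tables.
    Point estimates are kept at full precision either way.  Illogical
    estimates carry no interval.
    """
    results: dict[str, CorrectionResult] = {}
    for method in methods:
        result = _ANALYSIS_METHODS[method](cs.table, cs.ref)
        point_dp = 2 if (published_ci_convention and method != "classical") else None
        results[method] = estimators.attach_wilson_ci(
            result, cs.table, confidence=confidence, point_dp=point_dp
        )
    return results


def report_frame(case_ids: Sequence[str] = CASE_STUDY_IDS) -> pd.DataFrame:
    """Long-format report over case studies: one row per method per case."""
    rows = []
    for case_id in case_ids:
        cs = load_case_study(case_id)
        for method, result in analyze_case_study(cs).items():
            record = result.to_record()
            record.update(
                case=case_id,
                condition=cs.condition,
                description=cs.description,
                sn_rs=cs.ref.sn,
                sp_rs=cs.ref.sp,
            )
            rows.append(record)
    frame = pd.DataFrame(rows)
    lead = ["case", "condition", "description", "sn_rs", "sp_rs"]
    return frame[lead + [c for c in frame.columns if c not in lead]]
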