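"""End-to-end orchestration: validate, harmonize, score, band, report.

`run_reliability` produces one row per matched comparison in canonical
order, mirroring the side-by-side layout used to report instrument
agreement: domain, items on each side, applicable-review count, the Gwet
coefficient with its 95% CI, and the qualitative band.  Comparisons with
fewer than two applicable reviews are reported as not estimable rather
than dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .agreement import (
    AgreementResult,
    gwet_ac,
    identity_weights,
    quadratic_weights,
)
from .harmonization import (
    ComparisonSpec,
    comparison_table,
    coverage_stats,
    harmonize_all,
    unmatched_items,
)
from .instruments import (
    PairedAssessment,
    amstar2_overall,
    build_schema,
    validate_assessment,
    Instrument,
)

__all__ = ["RunConfig", "ReportRow", "run_reliability", "reliability_frame",
           "run_audit", "assess_ratings"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a reliability run."""

    alpha: float = 0.05
    digits: int = 2
    rule_e_mode: str = "ALL"
    strict_py_critical: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.digits < 0:
            raise ValueError("digits must be non-negative")


def _round(x: float, digits: int) -> float:
    return float(Decimal(repr(float(x))).quantize(
        Decimal(f"1e-{digits}"), rounding=ROUND_HALF_UP))


@dataclass
class ReportRow:
    """One comparison's agreement summary."""

    comparison_id: int
    domain: int
    label: str
    amstar_items: str
    robis_items: str
    weighting: str
    n_applicable: int
    n_excluded: int
    q: int
    estimable: bool
    estimate: float | None = None
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    band: str | None = None


def run_reliability(
    assessments: Sequence[PairedAssessment],
    config: RunConfig | None = None,
    table: Sequence[ComparisonSpec] | None = None,
) -> list[ReportRow]:
    """Harmonize every comparison and compute its agreement coefficient.

    The reliability path contains no randomness: identical inputs and
    config yield identical reports.
    """
    cfg = config or RunConfig()
    table = comparison_table() if table is None else table
    assessments = list(assessments)
    if not assessments:
        raise ValueError("no assessments provided")
    harmonized = harmonize_all(assessments, table, rule_e_mode=cfg.rule_e_mode)

    rows: list[ReportRow] = []
    for spec in table:
        hp = harmonized[spec.comparison_id]
        row = ReportRow(
            comparison_id=spec.comparison_id,
            domain=spec.domain,
            label=spec.label,
            amstar_items="+".join(spec.amstar_items),
            robis_items="+".join(spec.robis_items),
            weighting=spec.weighting,
            n_applicable=hp.n_applicable,
            n_excluded=hp.n_excluded,
            q=len(spec.scale),
            estimable=hp.n_applicable >= 2,
        )
        if row.estimable:
            weights = (
                quadratic_weights(len(spec.scale))
                if spec.weighting == "QUADRATIC"
                else identity_weights(len(spec.scale))
            )
            res: AgreementResult = gwet_ac(
                hp, weights=weights, alpha=cfg.alpha,
                ci=hp.n_applicable >= 3,
            )
            row.estimate = _round(res.estimate, cfg.digits)
            if hp.n_applicable >= 3:
                row.se = _round(res.se, cfg.digits + 2)
                row.ci_low = _round(res.ci_low, cfg.digits)
                row.ci_high = _round(res.ci_high, cfg.digits)
            row.band = res.band.value
        else:
            logger.warning(
                "comparison %d: only %d applicable review(s); not estimable",
                spec.comparison_id, hp.n_applicable,
            )
        rows.append(row)
    return rows


def reliability_frame(rows: Sequence[ReportRow]) -> pd.DataFrame:
    frame = pd.DataFrame([vars(r) for r in rows])
    frame["status"] = frame["estimable"].map(
        {True: "ESTIMABLE", False: "NOT_ESTIMABLE"}
    )
    return frame.drop(columns=["estimable"])


def run_audit() -> dict:
    """Structural audit of the canonical comparison table."""
    table = comparison_table()
    stats = coverage_stats(table)
    amstar_un, robis_un = unmatched_items(table)
    return {
        "n_comparisons": stats.n_comparisons,
        "n_amstar_matched": stats.n_amstar_matched,
        "n_robis_matched": stats.n_robis_matched,
        "n_items_total": 37,
        "pct_items_matched": stats.pct_items_matched,
        "n_fully_overlapping": stats.n_fully_overlapping,
        "amstar_unmatched": list(amstar_un),
        "robis_unmatched": list(robis_un),
    }


def assess_ratings(
    assessments: Sequence[PairedAssessment],
    strict_py_critical: bool = False,
) -> pd.DataFrame:
    """Per-review AMSTAR-2 overall confidence ratings."""
    records = []
    for pa in assessments:
        rating = amstar2_overall(pa, strict_py_critical=strict_py_critical)
        records.append(
            {
                "review_id": pa.review_id,
                "has_ma": pa.has_ma,
                "design_mix": pa.design_mix.value,
                "critical_flaws": rating.critical_flaws,
                "noncritical_flaws": rating.noncritical_flaws,
                "rating": rating.rating.value,
            }
        )
    return pd.DataFrame(records)


def validate_cohort(assessments: Sequence[PairedAssessment]) -> pd.DataFrame:
    """Validation report over a cohort: one row per violation."""
    a2 = build_schema(Instrument.AMSTAR2)
    rb = build_schema(Instrument.ROBIS)
    rows = []
    for pa in assessments:
        for v in validate_assessment(pa, a2, rb):
            rows.append(
                {
                    "review_id": v.review_id,
                    "instrument": v.instrument.value,
                    "item_id": v.item_id,
                    "message": v.message,
                }
            )
    return pd.DataFrame(rows, columns=["review_id", "instrument", "item_id", "message"])
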