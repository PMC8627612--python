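"""Response harmonization: the 11 matched AMSTAR-2/ROBIS comparisons.

The two instruments phrase overlapping methodological constructs with
different items and response alphabets, so item-level agreement can only be
measured after mapping both sides of each matched comparison onto a common
categorical scale.  The canonical matching pairs 12 AMSTAR-2 items with 14
ROBIS items in 11 comparisons across four domains; the remaining 4 AMSTAR-2
and 7 ROBIS items address constructs unique to their instrument.

The general translation collapses ROBIS to a binary verdict — ``Y``/``PY``
count as positive, ``N``/``PN``/``NI`` as negative — matched against
AMSTAR-2 ``Y`` vs ``N``.  Comparison-specific rules refine this:

* rule A — the AMSTAR-2 item admits PY; Y and PY merge with ROBIS Y/PY,
  leaving an unweighted binary comparison;
* rule B — AMSTAR-2 item 4 (search strategy) against ROBIS 2.1–2.4 on a
  three-level ordered scale N < PY < Y, scored with quadratic weights:
  the ROBIS side is Y when all four sub-items are positive, PY when 2.3
  and 2.4 are both positive, else N;
* rule C — AMSTAR-2 item 9 may be judged per study design; with both RCTs
  and NRSI included, the AMSTAR side is positive only when both strata are
  Y/PY;
* rule E — meta-analysis-gated; AMSTAR-2 item 11 (Y required, both strata
  when both designs) against the conjunction of ROBIS 4.3 and 4.4;
* rule F — AMSTAR-2 items 12+13 jointly against ROBIS 4.6; without a
  meta-analysis item 12 is NA and item 13 alone carries the comparison;
* rule G — default binary, but not considered for reviews without a
  meta-analysis.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .instruments import (
    DesignMix,
    Instrument,
    PairedAssessment,
    Response,
    ResponseLike,
    STRATA,
    build_schema,
    validate_assessment,
)

__all__ = [
    "Rule",
    "ComparisonSpec",
    "HarmonizedPairs",
    "CoverageStats",
    "HarmonizationError",
    "BINARY_SCALE",
    "ORDINAL3_SCALE",
    "comparison_table",
    "coverage_stats",
    "unmatched_items",
    "harmonize_robis_default",
    "harmonize_amstar_default",
    "harmonize_rule_b",
    "harmonize_rule_c",
    "harmonize_rule_e",
    "harmonize_rule_f",
    "harmonize_one",
    "harmonize_all",
    "table_to_json",
    "table_from_json",
]

logger = logging.getLogger(__name__)

POS = "POS"
NEG = "NEG"
BINARY_SCALE: tuple[str, str] = (NEG, POS)  # ordered NEG < POS
ORDINAL3_SCALE: tuple[str, str, str] = ("N", "PY", "Y")  # ordered N < PY < Y

_ROBIS_POSITIVE = frozenset({Response.Y, Response.PY})
_ROBIS_ALPHABET = frozenset(
    {Response.Y, Response.PY, Response.PN, Response.N, Response.NI}
)


class HarmonizationError(ValueError):
    """A response combination outside the rule's legal input alphabet."""


class Rule(str, enum.Enum):
    DEFAULT_BINARY = "DEFAULT_BINARY"
    A_BINARY_PYCOLLAPSE = "A_BINARY_PYCOLLAPSE"
    B_ORDINAL3_QUADRATIC = "B_ORDINAL3_QUADRATIC"
    C_DESIGN_CONDITIONAL = "C_DESIGN_CONDITIONAL"
    E_MA_DESIGN_CONDITIONAL = "E_MA_DESIGN_CONDITIONAL"
    F_MA_COMPOSITE = "F_MA_COMPOSITE"
    G_MA_CONDITIONAL = "G_MA_CONDITIONAL"


@dataclass(frozen=True)
class ComparisonSpec:
    """One matched-item comparison between the instruments."""

    comparison_id: int
    domain: int
    label: str
    amstar_items: tuple[str, ...]
    robis_items: tuple[str, ...]
    rule: Rule
    fully_overlapping: bool = True
    scale: tuple[str, ...] = BINARY_SCALE
    weighting: str = "IDENTITY"

    @property
    def ma_gated(self) -> bool:
        """Whether the whole comparison is skipped for reviews without MA."""
        return self.rule in (Rule.E_MA_DESIGN_CONDITIONAL, Rule.G_MA_CONDITIONAL)


def comparison_table() -> tuple[ComparisonSpec, ...]:
    """The canonical ordered table of the 11 matched comparisons."""
    return (
        ComparisonSpec(1, 1, "PICO components vs unambiguous eligibility criteria",
                       ("1",), ("1.3",), Rule.DEFAULT_BINARY),
        ComparisonSpec(2, 1, "A priori protocol vs adherence to predefined methods",
                       ("2",), ("1.1",), Rule.A_BINARY_PYCOLLAPSE),
        ComparisonSpec(3, 2, "Comprehensive search strategy vs search domain items",
                       ("4",), ("2.1", "2.2", "2.3", "2.4"),
                       Rule.B_ORDINAL3_QUADRATIC, scale=ORDINAL3_SCALE,
                       weighting="QUADRATIC"),
        ComparisonSpec(4, 2, "Duplicate study selection vs error minimization in selection",
                       ("5",), ("2.5",), Rule.DEFAULT_BINARY),
        ComparisonSpec(5, 3, "Duplicate data extraction vs error minimization in collection",
                       ("6",), ("3.1",), Rule.DEFAULT_BINARY),
        ComparisonSpec(6, 3, "Adequate study description vs sufficient study characteristics",
                       ("8",), ("3.2",), Rule.A_BINARY_PYCOLLAPSE),
        ComparisonSpec(7, 3, "Satisfactory RoB assessment vs formal RoB assessment",
                       ("9",), ("3.4",), Rule.C_DESIGN_CONDITIONAL),
        ComparisonSpec(8, 4, "Appropriate meta-analytic methods vs appropriate synthesis",
                       ("11",), ("4.3", "4.4"), Rule.E_MA_DESIGN_CONDITIONAL),
        ComparisonSpec(9, 4, "RoB impact on results/interpretation vs biases addressed",
                       ("12", "13"), ("4.6",), Rule.F_MA_COMPOSITE),
        ComparisonSpec(10, 4, "Heterogeneity explained vs heterogeneity addressed",
                       ("14",), ("4.4",), Rule.DEFAULT_BINARY),
        ComparisonSpec(11, 4, "Publication bias investigated vs robustness of findings",
                       ("15",), ("4.5",), Rule.G_MA_CONDITIONAL,
                       fully_overlapping=False),
    )


@dataclass(frozen=True)
class CoverageStats:
    """Structural summary of how much of the instruments the matching covers."""

    n_comparisons: int
    n_amstar_matched: int
    n_robis_matched: int
    pct_items_matched: float
    n_fully_overlapping: int


def _round_half_up(x: float, digits: int) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{digits}"), rounding=ROUND_HALF_UP))


def coverage_stats(table: Sequence[ComparisonSpec]) -> CoverageStats:
    """Item-coverage counts over the 16 + 21 = 37 instrument items."""
    amstar = {i for spec in table for i in spec.amstar_items}
    robis = {i for spec in table for i in spec.robis_items}
    pct = _round_half_up(100.0 * (len(amstar) + len(robis)) / 37.0, 1)
    return CoverageStats(
        n_comparisons=len(table),
        n_amstar_matched=len(amstar),
        n_robis_matched=len(robis),
        pct_items_matched=pct,
        n_fully_overlapping=sum(1 for spec in table if spec.fully_overlapping),
    )


def unmatched_items(
    table: Sequence[ComparisonSpec] | None = None,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Item ids of each instrument that no comparison uses, in schema order."""
    table = comparison_table() if table is None else table
    amstar = {i for spec in table for i in spec.amstar_items}
    robis = {i for spec in table for i in spec.robis_items}
    a2 = build_schema(Instrument.AMSTAR2)
    rb = build_schema(Instrument.ROBIS)
    return (
        tuple(i for i in a2.item_ids if i not in amstar),
        tuple(i for i in rb.item_ids if i not in robis),
    )


# ---------------------------------------------------------------------------
# harmonization rules


def _check_robis(resp: Response, item_id: str = "?") -> Response:
    if not isinstance(resp, Response) or resp not in _ROBIS_ALPHABET:
        raise HarmonizationError(
            f"ROBIS item {item_id}: {resp!r} is not a ROBIS response"
        )
    return resp


def harmonize_robis_default(resp: Response, item_id: str = "?") -> str:
    """Header rule for one ROBIS item: Y/PY → POS, N/PN/NI → NEG."""
    return POS if _check_robis(resp, item_id) in _ROBIS_POSITIVE else NEG


def harmonize_amstar_default(resp: Response, allows_py: bool, item_id: str = "?") -> str:
    """AMSTAR-2 side for default and rule-A comparisons.

    Y → POS, N → NEG; PY → POS only where the item admits PY (rule A).
    """
    if resp is Response.Y:
        return POS
    if resp is Response.N:
        return NEG
    if resp is Response.PY and allows_py:
        return POS
    raise HarmonizationError(
        f"AMSTAR-2 item {item_id}: illegal response {resp!r} for this comparison"
    )


def harmonize_rule_b(r21: Response, r22: Response, r23: Response, r24: Response) -> str:
    """ROBIS side of the search-strategy comparison, on N < PY < Y.

    Y when all of 2.1–2.4 are positive; PY when 2.3 and 2.4 are both
    positive (but not all four); otherwise N.
    """
    for item_id, r in (("2.1", r21), ("2.2", r22), ("2.3", r23), ("2.4", r24)):
        if r is None:
            raise HarmonizationError(f"ROBIS item {item_id}: missing response")
        _check_robis(r, item_id)
    if all(r in _ROBIS_POSITIVE for r in (r21, r22, r23, r24)):
        return "Y"
    if r23 in _ROBIS_POSITIVE and r24 in _ROBIS_POSITIVE:
        return "PY"
    return "N"


def _amstar_strata_positive(
    val: ResponseLike,
    design_mix: DesignMix,
    positive: frozenset[Response],
    item_id: str,
) -> bool:
    """Conjunctive stratum rule: positive iff every judged stratum is positive."""
    if isinstance(val, Mapping):
        if design_mix is not DesignMix.BOTH:
            raise HarmonizationError(
                f"AMSTAR-2 item {item_id}: per-stratum responses for a "
                f"{design_mix.value} review"
            )
        missing = [s for s in STRATA if s not in val]
        if missing:
            raise HarmonizationError(
                f"AMSTAR-2 item {item_id}: missing stratum {missing[0]}"
            )
        return all(val[s] in positive for s in STRATA)
    if design_mix is DesignMix.BOTH:
        raise HarmonizationError(
            f"AMSTAR-2 item {item_id}: expected RCT and NRSI responses for a "
            "review including both designs"
        )
    return val in positive


def harmonize_rule_c(
    a9: ResponseLike, r34: Response, design_mix: DesignMix
) -> tuple[str, str]:
    """Risk-of-bias-assessment comparison (AMSTAR-2 item 9 vs ROBIS 3.4).

    AMSTAR side positive iff the response is Y/PY — for reviews with both
    RCTs and NRSI, in both strata.  ROBIS side per the header rule.
    """
    a_pos = _amstar_strata_positive(a9, design_mix, _ROBIS_POSITIVE, "9")
    return (POS if a_pos else NEG, harmonize_robis_default(r34, "3.4"))


def harmonize_rule_e(
    a11: ResponseLike,
    r43: Response,
    r44: Response,
    has_ma: bool,
    design_mix: DesignMix,
    robis_combine: str = "ALL",
) -> tuple[str, str] | None:
    """Meta-analytic-methods comparison (AMSTAR-2 item 11 vs ROBIS 4.3 + 4.4).

    Not considered (returns None) without a meta-analysis.  The AMSTAR side
    requires Y — in both strata for reviews including both designs.  The
    ROBIS side combines 4.3 and 4.4: positive iff both are Y/PY
    (``robis_combine="ALL"``, default) or iff either is (``"ANY"``).
    """
    if not has_ma:
        return None
    if robis_combine not in ("ALL", "ANY"):
        raise ValueError(f"robis_combine must be ALL or ANY, got {robis_combine!r}")
    a_pos = _amstar_strata_positive(
        a11, design_mix, frozenset({Response.Y}), "11"
    )
    r_flags = (
        _check_robis(r43, "4.3") in _ROBIS_POSITIVE,
        _check_robis(r44, "4.4") in _ROBIS_POSITIVE,
    )
    r_pos = all(r_flags) if robis_combine == "ALL" else any(r_flags)
    return (POS if a_pos else NEG, POS if r_pos else NEG)


def harmonize_rule_f(
    a12: Response, a13: Response, r46: Response, has_ma: bool
) -> tuple[str, str]:
    """Bias-impact comparison (AMSTAR-2 items 12 + 13 vs ROBIS 4.6).

    Without a meta-analysis item 12 is NA and item 13 alone is compared
    (positive iff Y); with one, the AMSTAR side is positive iff both 12 and
    13 are Y.  ROBIS side per the header rule.
    """
    if has_ma:
        if a12 is Response.NA:
            raise HarmonizationError(
                "AMSTAR-2 item 12 is NA although the review has a meta-analysis"
            )
        a_pos = a12 is Response.Y and a13 is Response.Y
    else:
        if a12 is not Response.NA:
            raise HarmonizationError(
                f"AMSTAR-2 item 12 must be NA without a meta-analysis, got {a12!r}"
            )
        a_pos = a13 is Response.Y
    return (POS if a_pos else NEG, harmonize_robis_default(r46, "4.6"))


def harmonize_one(
    spec: ComparisonSpec,
    pa: PairedAssessment,
    rule_e_mode: str = "ALL",
) -> tuple[str, str] | None:
    """Harmonize one review for one comparison; None = not considered."""
    rule = spec.rule
    if rule is Rule.DEFAULT_BINARY or rule is Rule.A_BINARY_PYCOLLAPSE:
        (a_item,) = spec.amstar_items
        (r_item,) = spec.robis_items
        a_cat = harmonize_amstar_default(
            pa.amstar[a_item], rule is Rule.A_BINARY_PYCOLLAPSE, a_item
        )
        return (a_cat, harmonize_robis_default(pa.robis[r_item], r_item))
    if rule is Rule.B_ORDINAL3_QUADRATIC:
        a4 = pa.amstar["4"]
        if a4 not in (Response.Y, Response.PY, Response.N):
            raise HarmonizationError(f"AMSTAR-2 item 4: illegal response {a4!r}")
        r_cat = harmonize_rule_b(*(pa.robis[i] for i in ("2.1", "2.2", "2.3", "2.4")))
        return (a4.value, r_cat)
    if rule is Rule.C_DESIGN_CONDITIONAL:
        return harmonize_rule_c(pa.amstar["9"], pa.robis["3.4"], pa.design_mix)
    if rule is Rule.E_MA_DESIGN_CONDITIONAL:
        return harmonize_rule_e(
            pa.amstar["11"], pa.robis["4.3"], pa.robis["4.4"],
            pa.has_ma, pa.design_mix, robis_combine=rule_e_mode,
        )
    if rule is Rule.F_MA_COMPOSITE:
        a12, a13 = pa.amstar["12"], pa.amstar["13"]
        if isinstance(a12, Mapping) or isinstance(a13, Mapping):
            raise HarmonizationError("items 12/13 are not design-stratified")
        return harmonize_rule_f(a12, a13, pa.robis["4.6"], pa.has_ma)
    if rule is Rule.G_MA_CONDITIONAL:
        if not pa.has_ma:
            return None
        a15 = pa.amstar["15"]
        if isinstance(a15, Mapping):
            raise HarmonizationError("item 15 is not design-stratified")
        a_cat = harmonize_amstar_default(a15, False, "15")
        return (a_cat, harmonize_robis_default(pa.robis["4.5"], "4.5"))
    raise ValueError(f"unknown rule {rule!r}")  # pragma: no cover


@dataclass
class HarmonizedPairs:
    """Per-comparison harmonized (amstar, robis) category pairs."""

    comparison_id: int
    scale: tuple[str, ...]
    pairs: list[tuple[str, str]] = field(default_factory=list)
    review_ids: list[str] = field(default_factory=list)
    n_excluded: int = 0

    @property
    def n_applicable(self) -> int:
        return len(self.pairs)


def harmonize_all(
    assessments: Iterable[PairedAssessment],
    table: Sequence[ComparisonSpec] | None = None,
    rule_e_mode: str = "ALL",
    validate: bool = True,
) -> dict[int, HarmonizedPairs]:
    """Apply every comparison's rule to every review.

    Reviews failing validation are dropped from all comparisons with a
    logged warning (never silently imputed).  Meta-analysis-gated
    comparisons count their skipped reviews in ``n_excluded``, so
    ``n_applicable + n_excluded`` equals the number of (valid) reviews for
    every comparison.
    """
    table = comparison_table() if table is None else table
    a2 = build_schema(Instrument.AMSTAR2)
    rb = build_schema(Instrument.ROBIS)
    out = {
        spec.comparison_id: HarmonizedPairs(spec.comparison_id, spec.scale)
        for spec in table
    }
    for pa in assessments:
        if validate:
            violations = validate_assessment(pa, a2, rb)
            if violations:
                logger.warning(
                    "review %s dropped from all comparisons: %d validation "
                    "violation(s), first: %s",
                    pa.review_id, len(violations), violations[0].message,
                )
                continue
        for spec in table:
            try:
                cats = harmonize_one(spec, pa, rule_e_mode=rule_e_mode)
            except HarmonizationError as exc:
                raise HarmonizationError(
                    f"review {pa.review_id!r}, comparison {spec.comparison_id}: {exc}"
                ) from exc
            hp = out[spec.comparison_id]
            if cats is None:
                hp.n_excluded += 1
            else:
                hp.pairs.append(cats)
                hp.review_ids.append(pa.review_id)
    return out


# ---------------------------------------------------------------------------
# table (de)serialization for auditability


def table_to_json(table: Sequence[ComparisonSpec] | None = None) -> str:
    table = comparison_table() if table is None else table
    return json.dumps(
        [
            {
                "comparison_id": s.comparison_id,
                "domain": s.domain,
                "label": s.label,
                "amstar_items": list(s.amstar_items),
                "robis_items": list(s.robis_items),
                "rule": s.rule.value,
                "fully_overlapping": s.fully_overlapping,
                "scale": list(s.scale),
                "weighting": s.weighting,
            }
            for s in table
        ],
        indent=2,
    )


def table_from_json(text: str) -> tuple[ComparisonSpec, ...]:
    return tuple(
        ComparisonSpec(
            comparison_id=d["comparison_id"],
            domain=d["domain"],
            label=d["label"],
            amstar_items=tuple(d["amstar_items"]),
            robis_items=tuple(d["robis_items"]),
            rule=Rule(d["rule"]),
            fully_overlapping=d["fully_overlapping"],
            scale=tuple(d["scale"]),
            weighting=d["weighting"],
        )
        for d in json.loads(text)
    )
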