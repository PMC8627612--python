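"""AMSTAR-2 and ROBIS instrument schemas, response validation, and the
AMSTAR-2 overall-confidence algorithm.

AMSTAR-2 ("A Measurement Tool to Assess Systematic Reviews, version 2")
appraises systematic reviews of interventions with 16 items answered
``Y``/``N`` (five items additionally admit ``PY``, "partially yes").  Seven
items are *critical*: a single ``N`` on any of them caps the overall
confidence rating at LOW.  Items 11, 12 and 15 are answered only when the
review performed a meta-analysis; items 9 and 11 may carry separate
judgments for randomized (RCT) and non-randomized (NRSI) evidence when the
review includes both.

ROBIS ("Risk of Bias in Systematic reviews") assesses risk of bias with 21
signalling questions in four domains (eligibility criteria; identification
and selection; data collection and appraisal; synthesis and findings), each
answered on the five-level scale ``Y``/``PY``/``PN``/``N``/``NI``.

The schemas here are fixed constants of the published instruments; they are
exposed as frozen dataclasses so downstream harmonization and simulation
code can introspect item properties (criticality, PY-eligibility,
meta-analysis conditionality, design stratification) rather than hard-code
item ids.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Mapping, Union

__all__ = [
    "Response",
    "Instrument",
    "DesignMix",
    "ConfidenceRating",
    "ItemDef",
    "InstrumentSchema",
    "PairedAssessment",
    "Amstar2Rating",
    "Violation",
    "SchemaError",
    "ValidationError",
    "parse_response",
    "build_schema",
    "validate_assessment",
    "amstar2_overall",
    "robis_overall_heuristic",
    "AMSTAR2_CRITICAL_ITEMS",
    "AMSTAR2_PY_ITEMS",
    "AMSTAR2_MA_CONDITIONAL_ITEMS",
    "AMSTAR2_STRATIFIED_ITEMS",
    "ROBIS_DOMAIN_NAMES",
    "STRATA",
]


class SchemaError(ValueError):
    """Unknown instrument or malformed schema request."""


class ValidationError(ValueError):
    """An assessment failed validation where a valid one was required."""


class Response(str, enum.Enum):
    """Item-level response token shared by both instruments."""

    Y = "Y"
    PY = "PY"
    PN = "PN"
    N = "N"
    NI = "NI"
    NA = "NA"

    def __str__(self) -> str:  # serialize as the short token
        return self.value


_RESPONSE_SYNONYMS = {
    "Y": Response.Y,
    "YES": Response.Y,
    "PY": Response.PY,
    "PARTIAL YES": Response.PY,
    "PARTIALLY YES": Response.PY,
    "PN": Response.PN,
    "PARTIAL NO": Response.PN,
    "PARTIALLY NO": Response.PN,
    "N": Response.N,
    "NO": Response.N,
    "NI": Response.NI,
    "NO INFORMATION": Response.NI,
    "NA": Response.NA,
    "N/A": Response.NA,
    "NOT APPLICABLE": Response.NA,
    "": Response.NA,
}


def parse_response(token: Union[str, Response]) -> Response:
    """Parse a response token case-insensitively, accepting common synonyms.

    ``"Yes"`` → ``Y``, ``"Partially yes"`` → ``PY``, ``"No information"`` →
    ``NI``, ``"Not applicable"``/empty → ``NA``.
    """
    if isinstance(token, Response):
        return token
    key = str(token).strip().upper()
    try:
        return _RESPONSE_SYNONYMS[key]
    except KeyError:
        raise ValueError(f"unrecognized response token: {token!r}") from None


class Instrument(str, enum.Enum):
    AMSTAR2 = "AMSTAR2"
    ROBIS = "ROBIS"


class DesignMix(str, enum.Enum):
    """Study-design composition of the reviewed evidence base."""

    RCT_ONLY = "RCT_ONLY"
    NRSI_ONLY = "NRSI_ONLY"
    BOTH = "BOTH"


class ConfidenceRating(str, enum.Enum):
    """AMSTAR-2 overall confidence, ordered HIGH > MODERATE > LOW > CRITICALLY_LOW."""

    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    CRITICALLY_LOW = "CRITICALLY_LOW"

    @property
    def order(self) -> int:
        return {"HIGH": 3, "MODERATE": 2, "LOW": 1, "CRITICALLY_LOW": 0}[self.value]


STRATA = ("RCT", "NRSI")

AMSTAR2_CRITICAL_ITEMS = frozenset({"2", "4", "7", "9", "11", "13", "15"})
AMSTAR2_PY_ITEMS = frozenset({"2", "4", "7", "8", "9"})
AMSTAR2_MA_CONDITIONAL_ITEMS = frozenset({"11", "12", "15"})
AMSTAR2_STRATIFIED_ITEMS = frozenset({"9", "11"})

ROBIS_DOMAIN_NAMES = {
    1: "Study eligibility criteria",
    2: "Identification and selection of studies",
    3: "Data collection and study appraisal",
    4: "Synthesis and findings",
}

# Matched-domain label each AMSTAR-2 item carries for reporting (None = the
# item addresses a construct with no ROBIS counterpart).
_AMSTAR2_MATCHED_DOMAIN = {
    "1": 1, "2": 1, "3": None, "4": 2, "5": 2, "6": 3, "7": None, "8": 3,
    "9": 3, "10": None, "11": 4, "12": 4, "13": 4, "14": 4, "15": 4,
    "16": None,
}

_AMSTAR2_TEXT = {
    "1": "Research question and inclusion criteria include PICO components",
    "2": "Review methods established before conduct (protocol), deviations justified",
    "3": "Selection of study designs for inclusion explained",
    "4": "Comprehensive literature search strategy",
    "5": "Study selection performed in duplicate",
    "6": "Data extraction performed in duplicate",
    "7": "List of excluded studies provided with justification",
    "8": "Included studies described in adequate detail",
    "9": "Satisfactory technique for assessing risk of bias of included studies",
    "10": "Sources of funding of included studies reported",
    "11": "Appropriate methods for statistical combination of results",
    "12": "Potential impact of risk of bias on meta-analysis results assessed",
    "13": "Risk of bias accounted for when interpreting/discussing results",
    "14": "Satisfactory explanation and discussion of heterogeneity",
    "15": "Adequate investigation of publication bias and its likely impact",
    "16": "Potential sources of conflict of interest reported",
}

_ROBIS_TEXT = {
    "1.1": "Review adhered to predefined objectives and eligibility criteria",
    "1.2": "Eligibility criteria appropriate for the review question",
    "1.3": "Eligibility criteria unambiguous",
    "1.4": "Restrictions based on study characteristics appropriate",
    "1.5": "Restrictions based on sources of information appropriate",
    "2.1": "Appropriate range of databases/electronic sources searched",
    "2.2": "Methods additional to database searching used",
    "2.3": "Search terms and structure likely to retrieve as many eligible studies as possible",
    "2.4": "Restrictions based on date, publication format, or language appropriate",
    "2.5": "Efforts made to minimize error in selection of studies",
    "3.1": "Efforts made to minimize error in data collection",
    "3.2": "Sufficient study characteristics available to interpret results",
    "3.3": "All relevant study results collected for use in the synthesis",
    "3.4": "Risk of bias formally assessed using appropriate criteria",
    "3.5": "Efforts made to minimize error in risk of bias assessment",
    "4.1": "Synthesis included all studies that it should",
    "4.2": "All predefined analyses reported or departures explained",
    "4.3": "Synthesis appropriate given questions, study designs and outcomes",
    "4.4": "Between-study variation (heterogeneity) minimal or addressed",
    "4.5": "Findings robust (e.g. funnel plot, sensitivity analyses)",
    "4.6": "Biases in primary studies minimal or addressed in synthesis",
}


@dataclass(frozen=True)
class ItemDef:
    """Definition of a single instrument item.

    ``item_id`` is instrument-local: ``"1"``–``"16"`` for AMSTAR-2,
    ``"d.k"`` strings for ROBIS.  ``domain`` is the ROBIS domain for ROBIS
    items, and the matched reporting domain (or None) for AMSTAR-2 items.
    """

    item_id: str
    text: str
    critical: bool = False
    ma_conditional: bool = False
    allows_py: bool = False
    stratified_by_design: bool = False
    domain: int | None = None


@dataclass(frozen=True)
class InstrumentSchema:
    """Immutable schema of one instrument: items and domain grouping."""

    name: Instrument
    items: tuple[ItemDef, ...]
    domains: Mapping[int, tuple[str, ...]] = field(default_factory=dict)

    def item(self, item_id: str) -> ItemDef:
        try:
            return self._index[item_id]
        except KeyError:
            raise KeyError(f"{self.name.value} has no item {item_id!r}") from None

    @property
    def _index(self) -> dict[str, ItemDef]:
        # computed lazily; cached on the instance despite frozen-ness
        idx = self.__dict__.get("_index_cache")
        if idx is None:
            idx = {it.item_id: it for it in self.items}
            object.__setattr__(self, "_index_cache", idx)
        return idx

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def allowed_responses(self, item_id: str, has_ma: bool = True) -> frozenset[Response]:
        """Legal response set for an item given the review's MA status."""
        it = self.item(item_id)
        if self.name is Instrument.ROBIS:
            return frozenset({Response.Y, Response.PY, Response.PN, Response.N, Response.NI})
        if it.ma_conditional and not has_ma:
            return frozenset({Response.NA})
        allowed = {Response.Y, Response.N}
        if it.allows_py:
            allowed.add(Response.PY)
        return frozenset(allowed)

    def to_json(self) -> str:
        """Serialize the schema for external inspection."""
        payload = {
            "name": self.name.value,
            "items": [
                {
                    "item_id": it.item_id,
                    "text": it.text,
                    "critical": it.critical,
                    "ma_conditional": it.ma_conditional,
                    "allows_py": it.allows_py,
                    "stratified_by_design": it.stratified_by_design,
                    "domain": it.domain,
                }
                for it in self.items
            ],
            "domains": {str(d): list(ids) for d, ids in self.domains.items()},
        }
        return json.dumps(payload, indent=2)


def build_schema(name: Union[str, Instrument]) -> InstrumentSchema:
    """Return the fixed schema for ``AMSTAR2`` or ``ROBIS``.

    Raises :class:`SchemaError` for any other name.  Idempotent and
    side-effect free.
    """
    try:
        inst = Instrument(name) if not isinstance(name, Instrument) else name
    except ValueError:
        raise SchemaError(f"unknown instrument: {name!r}") from None

    if inst is Instrument.AMSTAR2:
        items = tuple(
            ItemDef(
                item_id=i,
                text=_AMSTAR2_TEXT[i],
                critical=i in AMSTAR2_CRITICAL_ITEMS,
                ma_conditional=i in AMSTAR2_MA_CONDITIONAL_ITEMS,
                allows_py=i in AMSTAR2_PY_ITEMS,
                stratified_by_design=i in AMSTAR2_STRATIFIED_ITEMS,
                domain=_AMSTAR2_MATCHED_DOMAIN[i],
            )
            for i in (str(k) for k in range(1, 17))
        )
        return InstrumentSchema(name=inst, items=items)

    items = tuple(
        ItemDef(
            item_id=f"{d}.{k}",
            text=_ROBIS_TEXT[f"{d}.{k}"],
            allows_py=True,
            domain=d,
        )
        for d in range(1, 5)
        for k in range(1, 7 if d == 4 else 6)
    )
    domains = {
        d: tuple(it.item_id for it in items if it.domain == d) for d in range(1, 5)
    }
    return InstrumentSchema(name=inst, items=items, domains=domains)


ResponseLike = Union[Response, Mapping[str, Response]]


@dataclass
class PairedAssessment:
    """One review's AMSTAR-2 and ROBIS item responses plus metadata.

    ``amstar`` maps item id → response; for stratified items (9, 11) of a
    review with ``design_mix=BOTH`` the value is a mapping
    ``{"RCT": resp, "NRSI": resp}``.  ``robis`` maps "d.k" → response.
    """

    review_id: str
    amstar: dict[str, ResponseLike]
    robis: dict[str, Response]
    has_ma: bool
    design_mix: DesignMix

    def amstar_responses(self, item_id: str) -> tuple[Response, ...]:
        """All responses recorded for an AMSTAR-2 item (1 or 2 strata)."""
        val = self.amstar[item_id]
        if isinstance(val, Mapping):
            return tuple(val[s] for s in STRATA if s in val)
        return (val,)


@dataclass(frozen=True)
class Amstar2Rating:
    """Overall AMSTAR-2 confidence with its flaw counts."""

    rating: ConfidenceRating
    critical_flaws: int
    noncritical_flaws: int


@dataclass(frozen=True)
class Violation:
    """One validation finding: violations are data, not exceptions."""

    review_id: str
    instrument: Instrument
    item_id: str | None
    message: str


def validate_assessment(
    pa: PairedAssessment,
    amstar_schema: InstrumentSchema | None = None,
    robis_schema: InstrumentSchema | None = None,
) -> list[Violation]:
    """Check one paired assessment against both schemas.

    Reports every missing item, illegal response for the item, ``NA`` on a
    non-conditional item, ``NA`` on a conditional item when the review has a
    meta-analysis, and missing or superfluous design strata.  An empty list
    means the assessment is valid.
    """
    a2 = amstar_schema or build_schema(Instrument.AMSTAR2)
    rb = robis_schema or build_schema(Instrument.ROBIS)
    out: list[Violation] = []

    def flag(inst: Instrument, item_id: str | None, msg: str) -> None:
        out.append(Violation(pa.review_id, inst, item_id, msg))

    for it in a2.items:
        if it.item_id not in pa.amstar:
            flag(Instrument.AMSTAR2, it.item_id, "missing response")
            continue
        val = pa.amstar[it.item_id]
        allowed = a2.allowed_responses(it.item_id, pa.has_ma)
        expect_strata = (
            it.stratified_by_design
            and pa.design_mix is DesignMix.BOTH
            and not (it.ma_conditional and not pa.has_ma)
        )
        if isinstance(val, Mapping):
            if not expect_strata:
                flag(Instrument.AMSTAR2, it.item_id,
                     "superfluous design strata for this item/design mix")
                continue
            missing = [s for s in STRATA if s not in val]
            extra = [s for s in val if s not in STRATA]
            for s in missing:
                flag(Instrument.AMSTAR2, it.item_id, f"missing stratum {s}")
            for s in extra:
                flag(Instrument.AMSTAR2, it.item_id, f"unknown stratum {s}")
            responses = [val[s] for s in STRATA if s in val]
        else:
            if expect_strata:
                flag(Instrument.AMSTAR2, it.item_id,
                     "expected per-stratum (RCT/NRSI) responses for this item")
                continue
            responses = [val]
        for r in responses:
            if not isinstance(r, Response):
                flag(Instrument.AMSTAR2, it.item_id, f"unparsed response {r!r}")
            elif r not in allowed:
                if r is Response.NA and not it.ma_conditional:
                    msg = "NA on a non-conditional item"
                elif it.ma_conditional and not pa.has_ma:
                    msg = f"must be NA when the review has no meta-analysis, got {r}"
                elif r is Response.NA:
                    msg = "NA on a conditional item although the review has a meta-analysis"
                else:
                    msg = f"illegal response {r} (allowed: {sorted(x.value for x in allowed)})"
                flag(Instrument.AMSTAR2, it.item_id, msg)

    for it in rb.items:
        if it.item_id not in pa.robis:
            flag(Instrument.ROBIS, it.item_id, "missing response")
            continue
        r = pa.robis[it.item_id]
        if not isinstance(r, Response) or r not in rb.allowed_responses(it.item_id):
            flag(Instrument.ROBIS, it.item_id, f"illegal response {r!r}")

    for extra_id in set(pa.amstar) - set(a2.item_ids):
        flag(Instrument.AMSTAR2, extra_id, "unknown item")
    for extra_id in set(pa.robis) - set(rb.item_ids):
        flag(Instrument.ROBIS, extra_id, "unknown item")
    return out


def amstar2_overall(
    pa: PairedAssessment,
    schema: InstrumentSchema | None = None,
    strict_py_critical: bool = False,
    validate: bool = True,
) -> Amstar2Rating:
    """Apply the AMSTAR-2 overall-confidence algorithm.

    A *flaw* is a response of ``N`` (for design-stratified items, ``N`` in
    any stratum); ``NA`` items are excluded from both flaw counts.  ``PY``
    counts as no flaw by default — the rating rule counts "major flaws" and
    PY is affirmative partial credit — but ``strict_py_critical=True``
    treats PY on a *critical* item as a flaw.

    Rating rule:

    * HIGH — no critical flaws and at most one non-critical flaw;
    * MODERATE — no critical flaws and more than one non-critical flaw;
    * LOW — exactly one critical flaw (any number of non-critical flaws);
    * CRITICALLY_LOW — more than one critical flaw.
    """
    schema = schema or build_schema(Instrument.AMSTAR2)
    if validate:
        violations = validate_assessment(pa, amstar_schema=schema)
        amstar_viol = [v for v in violations if v.instrument is Instrument.AMSTAR2]
        if amstar_viol:
            detail = "; ".join(f"item {v.item_id}: {v.message}" for v in amstar_viol[:5])
            raise ValidationError(
                f"review {pa.review_id!r}: invalid AMSTAR-2 assessment ({detail})"
            )

    critical = noncritical = 0
    for it in schema.items:
        responses = pa.amstar_responses(it.item_id)
        if all(r is Response.NA for r in responses):
            continue
        flaw = any(r is Response.N for r in responses)
        if strict_py_critical and it.critical:
            flaw = flaw or any(r is Response.PY for r in responses)
        if flaw:
            if it.critical:
                critical += 1
            else:
                noncritical += 1

    if critical > 1:
        rating = ConfidenceRating.CRITICALLY_LOW
    elif critical == 1:
        rating = ConfidenceRating.LOW
    elif noncritical > 1:
        rating = ConfidenceRating.MODERATE
    else:
        rating = ConfidenceRating.HIGH
    return Amstar2Rating(rating=rating, critical_flaws=critical,
                         noncritical_flaws=noncritical)


def robis_overall_heuristic(pa: PairedAssessment) -> str:
    """Convenience heuristic for an overall ROBIS impression.

    The published ROBIS guidance leaves the domain-concern and overall
    risk-of-bias judgments to the assessor; it defines no mechanical
    algorithm, so none is modelled here.  This helper exists only for rough
    triage and is excluded from the reliability pipeline: all items Y/PY →
    ``"low"``; any N/PN → ``"high"``; otherwise ``"unclear"``.
    """
    responses = list(pa.robis.values())
    if all(r in (Response.Y, Response.PY) for r in responses):
        return "low"
    if any(r in (Response.N, Response.PN) for r in responses):
        return "high"
    return "unclear"
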