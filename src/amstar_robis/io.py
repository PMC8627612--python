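"""Reading and writing assessments, metadata, truth tables and reports.

Long-format assessment CSV: one row per (review_id, instrument, item_id,
stratum, response); stratum is empty except for AMSTAR-2 items 9/11 of
reviews including both RCTs and NRSI.  Metadata CSV: one row per review
with ``has_ma`` and ``design_mix``.  An equivalent JSON layout stores one
object per review.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .instruments import (
    DesignMix,
    Instrument,
    PairedAssessment,
    Response,
    parse_response,
)
from .synthetic import SyntheticCohort

__all__ = [
    "write_assessments_csv",
    "read_assessments_csv",
    "write_assessments_json",
    "read_assessments_json",
    "write_truth_csv",
    "write_report",
    "read_report_json",
]

PathLike = Union[str, Path]

_ASSESSMENT_COLUMNS = ["review_id", "instrument", "item_id", "stratum", "response"]
_METADATA_COLUMNS = ["review_id", "has_ma", "design_mix"]


def _assessment_rows(assessments: Iterable[PairedAssessment]):
    for pa in assessments:
        for item_id, val in pa.amstar.items():
            if isinstance(val, Mapping):
                for stratum, resp in val.items():
                    yield (pa.review_id, "AMSTAR2", item_id, stratum, str(resp))
            else:
                yield (pa.review_id, "AMSTAR2", item_id, "", str(val))
        for item_id, resp in pa.robis.items():
            yield (pa.review_id, "ROBIS", item_id, "", str(resp))


def _metadata_frame(assessments: Sequence[PairedAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "review_id": [pa.review_id for pa in assessments],
            "has_ma": [str(pa.has_ma).lower() for pa in assessments],
            "design_mix": [pa.design_mix.value for pa in assessments],
        }
    )


def write_assessments_csv(
    assessments: Sequence[PairedAssessment],
    assessments_path: PathLike,
    metadata_path: PathLike,
) -> None:
    frame = pd.DataFrame(_assessment_rows(assessments), columns=_ASSESSMENT_COLUMNS)
    frame.to_csv(assessments_path, index=False)
    _metadata_frame(assessments).to_csv(metadata_path, index=False)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def read_assessments_csv(
    assessments_path: PathLike, metadata_path: PathLike
) -> list[PairedAssessment]:
    """Read the long-format CSV pair back into assessments.

    Responses are parsed case-insensitively with synonyms; review order
    follows first appearance in the assessment file.
    """
    frame = pd.read_csv(assessments_path, dtype=str, keep_default_na=False)
    missing = set(_ASSESSMENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"assessment CSV lacks columns: {sorted(missing)}")
    meta = pd.read_csv(metadata_path, dtype=str, keep_default_na=False)
    if set(_METADATA_COLUMNS) - set(meta.columns):
        raise ValueError(f"metadata CSV needs columns {_METADATA_COLUMNS}")
    meta_by_id = {
        row.review_id: (_parse_bool(row.has_ma), DesignMix(row.design_mix))
        for row in meta.itertuples()
    }

    order: list[str] = []
    amstar: dict[str, dict[str, object]] = {}
    robis: dict[str, dict[str, Response]] = {}
    for row in frame.itertuples():
        rid = row.review_id
        if rid not in amstar:
            order.append(rid)
            amstar[rid] = {}
            robis[rid] = {}
        resp = parse_response(row.response)
        inst = Instrument(row.instrument)
        if inst is Instrument.AMSTAR2:
            if row.stratum:
                slot = amstar[rid].setdefault(row.item_id, {})
                if not isinstance(slot, dict):
                    raise ValueError(
                        f"review {rid}: item {row.item_id} mixes plain and "
                        "per-stratum responses"
                    )
                slot[row.stratum] = resp
            else:
                amstar[rid][row.item_id] = resp
        else:
            robis[rid][row.item_id] = resp

    out = []
    for rid in order:
        if rid not in meta_by_id:
            raise ValueError(f"review {rid} has no metadata row")
        has_ma, design = meta_by_id[rid]
        out.append(
            PairedAssessment(
                review_id=rid, amstar=amstar[rid], robis=robis[rid],
                has_ma=has_ma, design_mix=design,
            )
        )
    return out


def write_assessments_json(
    assessments: Sequence[PairedAssessment], path: PathLike
) -> None:
    payload = []
    for pa in assessments:
        amstar = {
            item: ({s: str(r) for s, r in val.items()}
                   if isinstance(val, Mapping) else str(val))
            for item, val in pa.amstar.items()
        }
        payload.append(
            {
                "review_id": pa.review_id,
                "has_ma": pa.has_ma,
                "design_mix": pa.design_mix.value,
                "amstar": amstar,
                "robis": {item: str(r) for item, r in pa.robis.items()},
            }
        )
    Path(path).write_text(json.dumps(payload, indent=2))


def read_assessments_json(path: PathLike) -> list[PairedAssessment]:
    payload = json.loads(Path(path).read_text())
    out = []
    for obj in payload:
        amstar = {
            item: ({s: parse_response(r) for s, r in val.items()}
                   if isinstance(val, dict) else parse_response(val))
            for item, val in obj["amstar"].items()
        }
        robis = {item: parse_response(r) for item, r in obj["robis"].items()}
        out.append(
            PairedAssessment(
                review_id=obj["review_id"], amstar=amstar, robis=robis,
                has_ma=_parse_bool(obj["has_ma"]),
                design_mix=DesignMix(obj["design_mix"]),
            )
        )
    return out


def write_truth_csv(cohort: SyntheticCohort, items_path: PathLike,
                    reviews_path: PathLike | None = None) -> None:
    """Latent truth of a synthetic cohort, for recovery tests."""
    cohort.truth_items.to_csv(items_path, index=False)
    if reviews_path is not None:
        cohort.truth_reviews.to_csv(reviews_path, index=False)


def write_report(frame: pd.DataFrame, path: PathLike, fmt: str = "csv") -> None:
    """Write a reliability or rating report as CSV, JSON or aligned text."""
    path = Path(path)
    if fmt == "csv":
        frame.to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(frame.to_json(orient="records", indent=2))
    elif fmt == "table":
        path.write_text(frame.to_string(index=False) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r} (csv, json, table)")


def read_report_json(path: PathLike) -> pd.DataFrame:
    return pd.read_json(Path(path), orient="records")
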