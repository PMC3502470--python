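"""CSV/JSON readers and writers.

All tables are comma-separated UTF-8 with ``.`` as the decimal separator;
empty cells mark missing values.  Decimal-comma numbers (common in exported
German clinic data) are rejected with an explicit row issue rather than
silently misparsed.  JSON reports are written with sorted keys and no
timestamps, so a rerun over the same inputs is byte-identical.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .crosswalk import DerivedScores
from .errors import FormatError
from .instrument import (
    Demographics,
    InstrumentDefinition,
    MSQResponse,
)
from .scoring import ScoreReport
from .stats import ValidationResult, correlation_table, summary_table

_DEMOGRAPHIC_COLUMNS = [
    "respondent_id",
    "age",
    "sex",
    "affected_side",
    "hand_dominance",
    "employment",
    "pain_medication",
    "assessed_side",
    "completion_date",
    "diagnosis",
]
_ITEM_COLUMNS = [f"item_{i:02d}" for i in range(1, 31)]
MSQ_CSV_COLUMNS = _DEMOGRAPHIC_COLUMNS + _ITEM_COLUMNS + ["lifted_weight_kg"]


class RowIssue(Exception):
    """Internal: a cell in the current row cannot be parsed."""


def _cell(row: dict, col: str) -> Optional[str]:
    val = row.get(col)
    if val is None:
        return None
    val = val.strip()
    return val or None


def _parse_number(raw: str, col: str, kind=float):
    if "," in raw:
        raise RowIssue(
            f"column {col}: '{raw}' uses a decimal comma; use '.' as decimal separator"
        )
    try:
        return kind(raw)
    except ValueError as exc:
        raise RowIssue(f"column {col}: cannot parse '{raw}'") from exc


def read_responses(
    csv_path, instrument: InstrumentDefinition
) -> tuple[list[MSQResponse], list[str]]:
    """Read a respondent table into typed :class:`MSQResponse` records.

    Returns the parsed responses plus a list of row-level issues (with line
    numbers); a bad row is reported and skipped without aborting the file.

    Raises
    ------
    FormatError
        If the header does not contain the documented columns.
    """
    path = Path(csv_path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        required = {"respondent_id", "age", "sex", "affected_side",
                    "hand_dominance", "assessed_side", *_ITEM_COLUMNS}
        missing_cols = sorted(required - set(header))
        if missing_cols:
            raise FormatError(
                f"{path.name}: header is missing column(s) {missing_cols}"
            )

        responses: list[MSQResponse] = []
        issues: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                responses.append(_parse_row(row))
            except (RowIssue, ValueError) as exc:
                issues.append(f"{path.name}:{lineno}: {exc}")
        return responses, issues


def _parse_row(row: dict) -> MSQResponse:
    raw_date = _cell(row, "completion_date")
    demo = Demographics(
        respondent_id=_cell(row, "respondent_id") or "",
        age=_parse_number(_cell(row, "age") or "", "age"),
        sex=_cell(row, "sex") or "",
        affected_side=_cell(row, "affected_side") or "",
        hand_dominance=_cell(row, "hand_dominance") or "",
        employment=_cell(row, "employment") or "",
        pain_medication=_cell(row, "pain_medication") or "",
        assessed_side=_cell(row, "assessed_side") or "",
        completion_date=_dt.date.fromisoformat(raw_date) if raw_date else None,
        diagnosis=_cell(row, "diagnosis"),
    )
    answers: dict[int, int] = {}
    for i, col in enumerate(_ITEM_COLUMNS, start=1):
        raw = _cell(row, col)
        if raw is not None:
            answers[i] = _parse_number(raw, col, int)
    weight_raw = _cell(row, "lifted_weight_kg")
    weight = _parse_number(weight_raw, "lifted_weight_kg") if weight_raw else None
    return MSQResponse(demographics=demo, answers=answers, lifted_weight_kg=weight)


def write_responses(responses: Sequence[MSQResponse], csv_path) -> Path:
    """Write MSQ responses in the documented CSV layout."""
    path = Path(csv_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MSQ_CSV_COLUMNS)
        writer.writeheader()
        for resp in responses:
            d = resp.demographics
            row = {
                "respondent_id": d.respondent_id,
                "age": f"{d.age:g}",
                "sex": d.sex.value,
                "affected_side": d.affected_side.value,
                "hand_dominance": d.hand_dominance.value,
                "employment": d.employment,
                "pain_medication": d.pain_medication,
                "assessed_side": d.assessed_side.value,
                "completion_date": d.completion_date.isoformat()
                if d.completion_date
                else "",
                "diagnosis": d.diagnosis or "",
            }
            for i, col in enumerate(_ITEM_COLUMNS, start=1):
                row[col] = resp.answers.get(i, "")
            row["lifted_weight_kg"] = (
                f"{resp.lifted_weight_kg:g}" if resp.lifted_weight_kg is not None else ""
            )
            writer.writerow(row)
    return path


def write_cohort(patients, out_dir) -> dict[str, str]:
    """Write one CSV per instrument plus a manifest for a simulated cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    write_responses([p.msq_response for p in patients], out / "msq_responses.csv")

    spadi_cols = (
        ["respondent_id"]
        + [f"pain_{i:02d}" for i in range(1, 6)]
        + [f"disability_{i:02d}" for i in range(1, 9)]
    )
    with (out / "spadi_responses.csv").open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(spadi_cols)
        for p in patients:
            writer.writerow(
                [p.msq_response.demographics.respondent_id]
                + [f"{v:g}" for v in p.spadi_response.pain]
                + [f"{v:g}" for v in p.spadi_response.disability]
            )

    with (out / "dash_responses.csv").open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["respondent_id"] + _ITEM_COLUMNS)
        for p in patients:
            writer.writerow(
                [p.msq_response.demographics.respondent_id]
                + [f"{v:g}" for v in p.dash_response.items]
            )

    with (out / "cms_components.csv").open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["respondent_id", "pain", "adl", "rom", "strength"])
        for p in patients:
            c = p.cms_components
            writer.writerow(
                [p.msq_response.demographics.respondent_id]
                + [f"{v:g}" for v in (c.pain, c.adl, c.rom, c.strength)]
            )

    manifest = {
        "n_patients": len(patients),
        "files": {
            "msq": "msq_responses.csv",
            "spadi": "spadi_responses.csv",
            "dash": "dash_responses.csv",
            "cms": "cms_components.csv",
        },
    }
    with (out / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(out / v) for k, v in manifest["files"].items()}


def write_report(
    reports: Sequence[ScoreReport],
    derived: Sequence[DerivedScores] = (),
    validation: Sequence[ValidationResult] = (),
    out_dir=".",
    instrument_version: str = "",
    crosswalk_version: str = "",
) -> dict[str, Path]:
    """Write machine (JSON) and tabular (CSV) reports with provenance.

    Field order and key order are deterministic; no timestamps are embedded,
    so identical inputs yield byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    doc = {
        "instrument_version": instrument_version
        or (reports[0].instrument_version if reports else ""),
        "crosswalk_version": crosswalk_version
        or (derived[0].crosswalk_version if derived else ""),
        "scores": [r.model_dump() for r in reports],
        "derived": [d.model_dump() for d in derived],
        "validation": [v.model_dump() for v in validation],
    }
    report_json = out / "report.json"
    with report_json.open("w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    written["report_json"] = report_json

    if reports:
        frame = pd.DataFrame(
            [
                {
                    "respondent_id": r.respondent_id,
                    "raw": r.raw,
                    "percent": r.percent,
                    "percent_display": r.percent_display,
                    "objective_subtotal": r.objective_subtotal,
                    "subjective_subtotal": r.subjective_subtotal,
                    **{f"sub_{k.value}": v for k, v in r.subscale_subtotals.items()},
                    "complete": r.complete,
                    "prorated": r.prorated,
                }
                for r in reports
            ]
        )
        written["scores_csv"] = out / "scores.csv"
        frame.to_csv(written["scores_csv"], index=False)

    if derived:
        frame = pd.DataFrame([d.model_dump() for d in derived])
        written["derived_csv"] = out / "derived.csv"
        frame.to_csv(written["derived_csv"], index=False)

    if validation:
        written["summary_csv"] = out / "summary_table.csv"
        summary_table(validation).to_csv(written["summary_csv"])
        written["correlations_csv"] = out / "correlation_table.csv"
        correlation_table(validation).to_csv(written["correlations_csv"])

    return written


def write_plot_data(
    validation: Sequence[ValidationResult],
    pair_series: dict[str, tuple[Sequence[float], Sequence[float]]],
    out_dir,
) -> list[Path]:
    """Export scatter points and box summaries as CSV so the figures can be
    redrawn with any plotting stack."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for label, (orig, calc) in pair_series.items():
        path = out / f"scatter_{label}.csv"
        pd.DataFrame({"original": orig, "calculated": calc}).to_csv(path, index=False)
        written.append(path)
    rows = []
    for res in validation:
        for which, box in res.boxplots.items():
            rows.append(
                {
                    "pair": res.pair_label,
                    "series": which,
                    "median": box.median,
                    "q1": box.q1,
                    "q3": box.q3,
                    "whisker_lo": box.whisker_lo,
                    "whisker_hi": box.whisker_hi,
                    "n_outliers": len(box.outliers),
                    "outliers": ";".join(f"{v:g}" for v in box.outliers),
                }
            )
    path = out / "boxplots.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    written.append(path)
    return written
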