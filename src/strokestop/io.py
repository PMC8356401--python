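"""CSV cohort reading/writing, summary JSON, and the bundled cohort fixture.

Patient CSV schema (header mandatory; empty cells are missing values)::

    patient_id, group, psv_cm_s, edv_cm_s, sdvr, lp_pla2, lp_pla2_unit,
    plaque, stenosis_pct, hpx, il4, printed_index

``lp_pla2_unit`` accepts ug/l, ng/ml and mg/l as synonyms of the single
numeric scale used throughout. Files are comma-separated UTF-8 with "."
as the decimal separator.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .model import (
    Cohort,
    DuplexMeasurement,
    LP_PLA2_UNIT_SYNONYMS,
    PatientRecord,
    PlaqueEchogenicity,
    StenosisCategory,
    StenosisGrade,
    validate_record,
)
from .scoring import RiskResult

__all__ = [
    "COLUMNS",
    "ParseError",
    "EmptyInputError",
    "read_cohort",
    "write_cohort",
    "write_results",
    "load_table3",
    "table3_path",
]

COLUMNS = (
    "patient_id",
    "group",
    "psv_cm_s",
    "edv_cm_s",
    "sdvr",
    "lp_pla2",
    "lp_pla2_unit",
    "plaque",
    "stenosis_pct",
    "hpx",
    "il4",
    "printed_index",
)

_NUMERIC = ("psv_cm_s", "edv_cm_s", "sdvr", "lp_pla2", "stenosis_pct", "hpx", "il4", "printed_index")


class ParseError(ValueError):
    """A cohort file cell or header could not be parsed."""


class EmptyInputError(ValueError):
    """The cohort file holds no data rows."""


def _category_for_percent(pct: float) -> StenosisCategory:
    if pct >= 70:
        return StenosisCategory.GE70
    if pct >= 50:
        return StenosisCategory.S50_69
    return StenosisCategory.LT50


def _parse_row(row: pd.Series, row_no: int) -> PatientRecord:
    def num(col: str) -> float | None:
        raw = row.get(col)
        if raw is None or (isinstance(raw, str) and not raw.strip()) or pd.isna(raw):
            return None
        try:
            return float(raw)
        except (TypeError, ValueError):
            raise ParseError(f"row {row_no}, column {col!r}: not a number: {raw!r}") from None

    unit = row.get("lp_pla2_unit")
    if unit is not None and not pd.isna(unit) and str(unit).strip():
        if str(unit).strip().lower() not in LP_PLA2_UNIT_SYNONYMS:
            raise ParseError(
                f"row {row_no}, column 'lp_pla2_unit': unknown unit {unit!r}; "
                f"accepted synonyms: {sorted(LP_PLA2_UNIT_SYNONYMS)}"
            )

    plaque_raw = row.get("plaque")
    plaque = None
    if plaque_raw is not None and not pd.isna(plaque_raw) and str(plaque_raw).strip():
        try:
            plaque = PlaqueEchogenicity.parse(str(plaque_raw))
        except ValueError as exc:
            raise ParseError(f"row {row_no}, column 'plaque': {exc}") from None

    psv, edv = num("psv_cm_s"), num("edv_cm_s")
    if (psv is None) != (edv is None):
        raise ParseError(f"row {row_no}: psv_cm_s and edv_cm_s must be given together")
    duplex = DuplexMeasurement(psv=psv, edv=edv) if psv is not None else None

    pct = num("stenosis_pct")
    stenosis = (
        StenosisGrade(category=_category_for_percent(pct), percent=pct) if pct is not None else None
    )

    group_raw = row.get("group")
    group = (
        str(group_raw).strip().lower()
        if group_raw is not None and not pd.isna(group_raw) and str(group_raw).strip()
        else None
    )

    pid_raw = row.get("patient_id")
    if pid_raw is None or pd.isna(pid_raw) or not str(pid_raw).strip():
        raise ParseError(f"row {row_no}, column 'patient_id': missing")

    return PatientRecord(
        patient_id=str(pid_raw).strip(),
        group=group,
        duplex=duplex,
        sdvr=num("sdvr"),
        lp_pla2=num("lp_pla2"),
        plaque=plaque,
        stenosis=stenosis,
        hpx=num("hpx"),
        il4=num("il4"),
        printed_index=num("printed_index"),
    )


def read_cohort(path, strict: bool = False, provenance: str | None = None) -> Cohort:
    """Read a patient CSV into a Cohort.

    Per-row validation violations are collected on ``cohort.violations``
    (a list of ``(row_number, message)``); with ``strict=True`` any
    violation aborts with a ParseError. Malformed cells always raise.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    missing = {"patient_id", "lp_pla2", "plaque"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: header is missing required columns {sorted(missing)}")
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")

    records: list[PatientRecord] = []
    violations: list[tuple[int, str]] = []
    for i, (_, row) in enumerate(df.iterrows()):
        row_no = i + 2  # 1-based, after the header line
        rec = _parse_row(row, row_no)
        for msg in validate_record(rec):
            violations.append((row_no, msg))
        records.append(rec)
    if strict and violations:
        detail = "; ".join(f"row {r}: {m}" for r, m in violations[:5])
        raise ParseError(f"{path}: {len(violations)} validation violation(s): {detail}")
    cohort = Cohort(records=records, provenance=provenance or str(path))
    cohort.violations = violations  # type: ignore[attr-defined]
    return cohort


def _fmt(value, decimals: int | None = None) -> str:
    if value is None:
        return ""
    if decimals is not None:
        return f"{value:.{decimals}f}"
    return f"{value:g}"


def write_cohort(cohort: Cohort, path) -> Path:
    """Write a cohort in the patient CSV schema (SDVR to 6 decimals)."""
    rows = []
    for rec in cohort:
        rows.append(
            {
                "patient_id": rec.patient_id,
                "group": rec.group or "",
                "psv_cm_s": _fmt(rec.duplex.psv if rec.duplex else None),
                "edv_cm_s": _fmt(rec.duplex.edv if rec.duplex else None),
                "sdvr": _fmt(rec.sdvr, 6) if rec.sdvr is not None else "",
                "lp_pla2": _fmt(rec.lp_pla2, 4) if rec.lp_pla2 is not None else "",
                "lp_pla2_unit": "ug/l" if rec.lp_pla2 is not None else "",
                "plaque": rec.plaque.value if rec.plaque else "",
                "stenosis_pct": _fmt(rec.stenosis.percent if rec.stenosis else None),
                "hpx": _fmt(rec.hpx),
                "il4": _fmt(rec.il4),
                "printed_index": _fmt(rec.printed_index),
            }
        )
    path = Path(path)
    pd.DataFrame(rows, columns=list(COLUMNS)).to_csv(path, index=False)
    return path


def write_results(cohort: Cohort, results: dict[str, RiskResult], summary, out_dir) -> dict:
    """Write per-patient results CSV and a summary JSON under ``out_dir``.

    ``results`` maps patient_id to RiskResult for every scored record (an
    unscored cohort — empty results — is a precondition failure). Indices
    are serialized to 4 decimals.
    """
    if not results:
        raise ValueError("refusing to write an unscored cohort (no results)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        res = results.get(rec.patient_id)
        if res is None:
            continue
        rows.append(
            {
                "patient_id": rec.patient_id,
                "index": f"{res.index:.4f}",
                "band": res.band,
                "area": f"{res.area:.4f}",
                "sf": res.sf,
            }
        )
    results_path = out_dir / "results.csv"
    pd.DataFrame(rows, columns=["patient_id", "index", "band", "area", "sf"]).to_csv(
        results_path, index=False
    )
    summary_path = out_dir / "summary.json"
    payload = summary.to_dict() if hasattr(summary, "to_dict") else dataclasses.asdict(summary)
    summary_path.write_text(json.dumps(payload, indent=2) + "\n")
    return {"results": results_path, "summary": summary_path}


def table3_path() -> Path:
    """Filesystem path of the bundled 70-patient cohort table."""
    return Path(resources.files("strokestop.data") / "table3.csv")


def load_table3() -> Cohort:
    """The bundled 70-patient cohort table as a Cohort.

    Rows carry the published index (``printed_index``), Lp-PLA2, plaque
    class and stenosis percent; the symptomatic/asymptomatic flag is not
    carried (its per-row assignment is ambiguous in the source), so
    ``group`` is unset.
    """
    return read_cohort(table3_path(), provenance="fixture:table3")
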