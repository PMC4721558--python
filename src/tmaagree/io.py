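"""Reading and writing the delimited panel table.

Dialect: comma-separated, UTF-8, one row per (case, TMA) with a fixed
header.  Binary marker cells are ``pos``/``neg``/``NA``; HER2 cells are
``neg``/``1+``/``2+``/``3+``/``NA``; ``ki67_percent`` is a decimal or
``NA``.  The bundled ``table1`` fixture transcribes the 30-case
reference study (5 cases per decade, duplicate TMAs, one fully-missing
panel) and can be loaded by name.
"""

from __future__ import annotations

import csv
import importlib.resources
from pathlib import Path
from typing import List, Optional, Union

from .dataset import CaseRecord, DatasetError, StudyDataset, TmaPanel, decade_of
from .markers import parse_her2, parse_marker

HEADER = [
    "case_id",
    "tma_id",
    "year",
    "histology",
    "grade",
    "ck_cocktail",
    "er",
    "pr",
    "her2",
    "ck56",
    "egfr",
    "ki67_percent",
    "printed_phenotype",
]

FIXTURE_NAMES = ("table1",)


def fixture_path(name: str) -> Path:
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    return Path(str(importlib.resources.files("tmaagree") / "fixtures" / f"{name}.csv"))


def load_table1() -> StudyDataset:
    """Load the packaged 30-case reference study."""
    return read_dataset(fixture_path("table1"))


def _parse_ki67(cell: str, row_no: int, errors: List[str]) -> Optional[float]:
    cell = cell.strip()
    if cell == "" or cell.upper() == "NA":
        return None
    try:
        value = float(cell)
    except ValueError:
        errors.append(f"row {row_no}: ki67_percent not numeric: {cell!r}")
        return None
    if not 0.0 <= value <= 100.0:
        errors.append(f"row {row_no}: ki67_percent out of [0, 100]: {value}")
        return None
    return value


def read_dataset(path: Union[str, Path]) -> StudyDataset:
    """Parse a panel table; raises :class:`DatasetError` listing every bad row."""
    path = Path(path)
    errors: List[str] = []
    cases: dict = {}
    panels: List[TmaPanel] = []
    seen_panels = set()
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            return StudyDataset(cases=[], panels=[])
        if [h.strip() for h in header] != HEADER:
            raise DatasetError(
                [f"unexpected header {header!r}; expected {HEADER!r}"]
            )
        for row_no, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            if len(row) != len(HEADER):
                errors.append(
                    f"row {row_no}: expected {len(HEADER)} fields, got {len(row)}"
                )
                continue
            rec = dict(zip(HEADER, (cell.strip() for cell in row)))
            case_id = rec["case_id"]
            try:
                year = int(rec["year"])
                decade_of(year)
            except ValueError:
                errors.append(f"row {row_no}: bad diagnosis year {rec['year']!r}")
                continue
            try:
                grade = int(rec["grade"])
            except ValueError:
                errors.append(f"row {row_no}: bad grade {rec['grade']!r}")
                continue
            try:
                case = CaseRecord(case_id, year, rec["histology"], grade)
            except ValueError as exc:
                errors.append(f"row {row_no}: {exc}")
                continue
            if case_id in cases:
                if cases[case_id] != case:
                    errors.append(
                        f"row {row_no}: case {case_id!r} repeated with "
                        "conflicting case-level fields"
                    )
            else:
                cases[case_id] = case
            key = (case_id, rec["tma_id"])
            if key in seen_panels:
                errors.append(
                    f"row {row_no}: duplicate panel for case {case_id!r} "
                    f"{rec['tma_id']}"
                )
                continue
            seen_panels.add(key)
            try:
                marker_calls = {m: parse_marker(rec[m]) for m in
                                ("ck_cocktail", "er", "pr", "ck56", "egfr")}
                her2 = parse_her2(rec["her2"])
            except ValueError as exc:
                errors.append(f"row {row_no}: {exc}")
                continue
            ki67 = _parse_ki67(rec["ki67_percent"], row_no, errors)
            printed = rec["printed_phenotype"] or None
            if printed is not None and printed.upper() == "NA":
                printed = None
            try:
                panels.append(
                    TmaPanel(
                        case_id=case_id,
                        tma_id=rec["tma_id"],
                        her2=her2,
                        ki67_percent=ki67,
                        printed_phenotype=printed,
                        **marker_calls,
                    )
                )
            except ValueError as exc:
                errors.append(f"row {row_no}: {exc}")
    if errors:
        raise DatasetError(errors)
    return StudyDataset(cases=list(cases.values()), panels=panels)


def _format_ki67(value: Optional[float]) -> str:
    if value is None:
        return "NA"
    return repr(value)  # shortest exact decimal, so the round trip is lossless


def write_dataset(ds: StudyDataset, path: Union[str, Path]) -> Path:
    """Write a dataset in the panel-table dialect.

    ``read_dataset(write_dataset(ds))`` equals ``ds`` on typed values for
    any dataset in which every case carries at least one panel; case-level
    fields travel on the panel rows, so a panel-less case has no carrier
    row in this dialect.
    """
    path = Path(path)
    case_by_id = {c.case_id: c for c in ds.cases}
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(HEADER)
        for panel in ds.panels:
            case = case_by_id[panel.case_id]
            writer.writerow(
                [
                    panel.case_id,
                    panel.tma_id,
                    case.diagnosis_year,
                    case.histology,
                    case.grade,
                    panel.ck_cocktail.value,
                    panel.er.value,
                    panel.pr.value,
                    panel.her2.value,
                    panel.ck56.value,
                    panel.egfr.value,
                    _format_ki67(panel.ki67_percent),
                    panel.printed_phenotype or "NA",
                ]
            )
    return path
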