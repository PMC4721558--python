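"""Case records, per-TMA marker panels, and whole-study datasets.

A study consists of tumor cases sampled by decade of diagnosis
(1947-1959, then calendar decades through 2000-2009) and, for each case,
up to two marker panels — one per duplicate tissue microarray (TMA).
Each panel carries the TMA-level call for every stain after core
aggregation.  A panel may be fully missing (the specimen contributed no
evaluable tissue to that TMA) and still be a first-class row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

from .markers import Her2Score, MarkerCall, validate_ki67

#: Diagnosis-year strata: the first spans 1947-1959, the rest are decades.
DECADE_STRATA: Tuple[Tuple[int, int], ...] = (
    (1947, 1959),
    (1960, 1969),
    (1970, 1979),
    (1980, 1989),
    (1990, 1999),
    (2000, 2009),
)

DECADE_LABELS: Tuple[str, ...] = tuple(f"{lo}-{hi}" for lo, hi in DECADE_STRATA)

TMA_IDS = ("TMA1", "TMA2")

BINARY_MARKERS = ("ck_cocktail", "er", "pr", "ck56", "egfr")


class DatasetError(ValueError):
    """Aggregated validation failure; ``errors`` lists row-level messages."""

    def __init__(self, errors: List[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def decade_of(year: int) -> str:
    """Map a diagnosis year to its stratum label, e.g. ``1955 -> '1947-1959'``."""
    for (lo, hi), label in zip(DECADE_STRATA, DECADE_LABELS):
        if lo <= year <= hi:
            return label
    raise ValueError(f"diagnosis year {year} outside the study range 1947-2009")


@dataclass(frozen=True)
class CaseRecord:
    case_id: str
    diagnosis_year: int
    histology: str
    grade: int

    def __post_init__(self) -> None:
        decade_of(self.diagnosis_year)  # raises if out of range
        if self.grade not in (1, 2, 3):
            raise ValueError(
                f"case {self.case_id}: histologic grade must be 1, 2 or 3, "
                f"got {self.grade!r}"
            )

    @property
    def decade(self) -> str:
        return decade_of(self.diagnosis_year)


@dataclass(frozen=True)
class TmaPanel:
    """TMA-level marker results for one case on one replicate array."""

    case_id: str
    tma_id: str
    ck_cocktail: MarkerCall = MarkerCall.MISSING
    er: MarkerCall = MarkerCall.MISSING
    pr: MarkerCall = MarkerCall.MISSING
    her2: Her2Score = Her2Score.MISSING
    ck56: MarkerCall = MarkerCall.MISSING
    egfr: MarkerCall = MarkerCall.MISSING
    ki67_percent: Optional[float] = None
    printed_phenotype: Optional[str] = None  # validation text, never an input

    def __post_init__(self) -> None:
        if self.tma_id not in TMA_IDS:
            raise ValueError(f"tma_id must be one of {TMA_IDS}, got {self.tma_id!r}")
        object.__setattr__(self, "ki67_percent", validate_ki67(self.ki67_percent))

    @property
    def is_fully_missing(self) -> bool:
        return (
            all(getattr(self, m) is MarkerCall.MISSING for m in BINARY_MARKERS)
            and self.her2 is Her2Score.MISSING
            and self.ki67_percent is None
        )

    def without_printed(self) -> "TmaPanel":
        return replace(self, printed_phenotype=None)


@dataclass
class StudyDataset:
    """All case records plus up to two panels per case."""

    cases: List[CaseRecord] = field(default_factory=list)
    panels: List[TmaPanel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        errors: List[str] = []
        seen_cases: Dict[str, CaseRecord] = {}
        for case in self.cases:
            if case.case_id in seen_cases:
                errors.append(f"duplicate case_id {case.case_id!r}")
            seen_cases[case.case_id] = case
        seen_panels = set()
        for panel in self.panels:
            key = (panel.case_id, panel.tma_id)
            if key in seen_panels:
                errors.append(f"duplicate panel for case {key[0]!r} {key[1]}")
            seen_panels.add(key)
            if panel.case_id not in seen_cases:
                errors.append(
                    f"panel references unknown case_id {panel.case_id!r}"
                )
        if errors:
            raise DatasetError(errors)

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def case(self, case_id: str) -> CaseRecord:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise KeyError(case_id)

    def panel(self, case_id: str, tma_id: str) -> Optional[TmaPanel]:
        for p in self.panels:
            if p.case_id == case_id and p.tma_id == tma_id:
                return p
        return None

    def panels_for(self, case_id: str) -> List[TmaPanel]:
        return [p for p in self.panels if p.case_id == case_id]

    def cases_per_decade(self) -> Dict[str, int]:
        counts = {label: 0 for label in DECADE_LABELS}
        for case in self.cases:
            counts[case.decade] += 1
        return counts

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyDataset):
            return NotImplemented
        return self.cases == other.cases and self.panels == other.panels
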