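"""Core-to-TMA aggregation rules and the antigen-integrity check.

Each specimen contributes three 0.6-mm cores to each TMA.  A binary
stain is positive at the TMA level if one or more cores are positive,
negative if at least one core bears tissue and none is positive, and
missing when no core has evaluable tissue.  HER2 takes the maximum
ordinal score over tissue-bearing cores; Ki67 averages percent-positive
over tissue-bearing cores.  The CK-cocktail stain serves as a control
for antigen preservation: a case fails integrity when every evaluable
CK-cocktail call across both TMAs is negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Union

from .dataset import StudyDataset, TmaPanel
from .markers import Her2Score, MarkerCall, validate_ki67

CoreResult = Union[MarkerCall, Her2Score, float, None]


@dataclass(frozen=True)
class CoreScore:
    """One core's raw staining result for one marker.

    ``result`` is a :class:`MarkerCall` for binary stains, a
    :class:`Her2Score` for HER2, or a percent for Ki67; it must encode
    missing whenever ``tissue_present`` is false.
    """

    case_id: str
    tma_id: str
    core_index: int
    marker: str
    result: CoreResult
    tissue_present: bool = True

    def __post_init__(self) -> None:
        if self.core_index < 1:
            raise ValueError("core_index starts at 1")
        if not self.tissue_present and not self._result_missing():
            raise ValueError(
                f"core {self.case_id}/{self.tma_id}#{self.core_index} "
                f"({self.marker}): result present but tissue_present=False"
            )
        if isinstance(self.result, float):
            validate_ki67(self.result)

    def _result_missing(self) -> bool:
        return (
            self.result is None
            or self.result is MarkerCall.MISSING
            or self.result is Her2Score.MISSING
        )


@dataclass(frozen=True)
class IntegrityFlag:
    case_id: str
    preserved: bool


def _check_cores(cores: Sequence[CoreScore]) -> None:
    if not cores:
        raise ValueError("cannot aggregate an empty list of cores")
    keys = {(c.case_id, c.tma_id, c.marker) for c in cores}
    if len(keys) != 1:
        raise ValueError(f"cores mix panels/markers: {sorted(keys)}")
    if not 1 <= len(cores) <= 3:
        raise ValueError(f"expected 1-3 cores per panel, got {len(cores)}")


def aggregate_binary_marker(cores: Sequence[CoreScore]) -> MarkerCall:
    """Positive if any core positive; negative if evaluable and none positive."""
    _check_cores(cores)
    evaluable = [c for c in cores if c.tissue_present]
    if not evaluable:
        return MarkerCall.MISSING
    calls = [c.result for c in evaluable]
    if any(call is MarkerCall.POSITIVE for call in calls):
        return MarkerCall.POSITIVE
    if any(call is MarkerCall.NEGATIVE for call in calls):
        return MarkerCall.NEGATIVE
    return MarkerCall.MISSING


def aggregate_her2(cores: Sequence[CoreScore]) -> Her2Score:
    """Maximum ordinal HER2 score over tissue-bearing cores."""
    _check_cores(cores)
    scores = [
        c.result
        for c in cores
        if c.tissue_present and isinstance(c.result, Her2Score) and c.result.is_definite
    ]
    if not scores:
        return Her2Score.MISSING
    return max(scores, key=lambda s: s.rank)


def aggregate_ki67(cores: Sequence[CoreScore]) -> Optional[float]:
    """Mean percent-positive over tissue-bearing cores; ``None`` if none."""
    _check_cores(cores)
    values = [
        validate_ki67(c.result)
        for c in cores
        if c.tissue_present and c.result is not None
    ]
    if not values:
        return None
    return float(sum(values)) / len(values)


def aggregate_panel(
    case_id: str, tma_id: str, cores: Iterable[CoreScore]
) -> TmaPanel:
    """Assemble a TMA-level panel from this panel's core records."""
    by_marker: Dict[str, List[CoreScore]] = {}
    for core in cores:
        if core.case_id != case_id or core.tma_id != tma_id:
            raise ValueError(
                f"core {core.case_id}/{core.tma_id} does not belong to "
                f"panel {case_id}/{tma_id}"
            )
        by_marker.setdefault(core.marker, []).append(core)

    def binary(marker: str) -> MarkerCall:
        if marker not in by_marker:
            return MarkerCall.MISSING
        return aggregate_binary_marker(by_marker[marker])

    her2 = aggregate_her2(by_marker["her2"]) if "her2" in by_marker else Her2Score.MISSING
    ki67 = aggregate_ki67(by_marker["ki67"]) if "ki67" in by_marker else None
    return TmaPanel(
        case_id=case_id,
        tma_id=tma_id,
        ck_cocktail=binary("ck_cocktail"),
        er=binary("er"),
        pr=binary("pr"),
        her2=her2,
        ck56=binary("ck56"),
        egfr=binary("egfr"),
        ki67_percent=ki67,
    )


def antigen_integrity(case_id: str, panels: Sequence[TmaPanel]) -> IntegrityFlag:
    """Case-level antigen-preservation verdict from CK-cocktail calls.

    Not preserved only when at least one CK-cocktail call is evaluable and
    every evaluable call (across both TMAs) is negative; a single positive
    call, or no evaluable call at all, counts as preserved.
    """
    if not panels:
        raise ValueError(f"case {case_id!r}: integrity needs at least one panel")
    calls = [p.ck_cocktail for p in panels if p.case_id == case_id]
    if len(calls) != len(panels):
        raise ValueError(f"panels do not all belong to case {case_id!r}")
    definite = [c for c in calls if c.is_definite]
    failed = bool(definite) and all(c is MarkerCall.NEGATIVE for c in definite)
    return IntegrityFlag(case_id=case_id, preserved=not failed)


def integrity_summary(ds: StudyDataset) -> Dict[str, bool]:
    """Map every case with at least one panel to its preservation verdict."""
    out: Dict[str, bool] = {}
    for case in ds.cases:
        panels = ds.panels_for(case.case_id)
        if panels:
            out[case.case_id] = antigen_integrity(case.case_id, panels).preserved
    return out
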