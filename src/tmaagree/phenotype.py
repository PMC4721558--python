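"""Surrogate molecular-phenotype classification from the immunostain panel.

The classifier assigns the standard IHC surrogate subtypes:

* Luminal A    — ER+ and/or PR+, HER2-, Ki67 < cutoff (default 14%)
* Luminal B    — ER+ and/or PR+ and HER2+; or ER+ and/or PR+, HER2-,
                 Ki67 >= cutoff
* HER2-enriched — ER- and PR-, HER2+
* Basal-like   — ER-, PR-, HER2-, and CK 5/6+ and/or EGFR+
* Unclassifiable — ER-, PR-, HER2-, CK 5/6-, EGFR-

HER2 positivity for classification counts only 3+ by default (2+ cases
without reflex in-situ hybridization are treated as negative, which is
what the reference calls require).  Missing markers are handled by
enumerating every completion of the missing values: if all completions
agree the call is definite; if they disagree, the call is an explicit
ambiguous candidate set — unless the observed hormone-receptor pair is
itself equivocal (ER and PR definite but discordant), in which case the
phenotype is reported as unknown.  A panel with both ER and PR missing
is always unknown.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, Optional, Tuple

from .dataset import StudyDataset, TmaPanel
from .markers import Her2Score, MarkerCall


class Subtype(enum.Enum):
    LUMINAL_A = "Luminal A"
    LUMINAL_B = "Luminal B"
    HER2_ENRICHED = "HER2"
    BASAL_LIKE = "Basal-like"
    UNCLASSIFIABLE = "Unclassifiable"


class CallKind(enum.Enum):
    DEFINITE = "definite"
    AMBIGUOUS = "ambiguous"
    UNKNOWN = "unknown"


_DEFAULT_HER2_POSITIVE = frozenset({Her2Score.THREE_PLUS})


@dataclass(frozen=True)
class PhenotypeRules:
    """Tunable classification conventions.

    ``ki67_cutoff`` separates Luminal A from Luminal B among
    HER2-negative hormone-receptor-positive tumors; the boundary value
    itself counts as high.  ``her2_positive_levels`` lists the ordinal
    HER2 levels treated as positive for classification and must be
    upward-closed on the 0/1+/2+/3+ scale.
    """

    ki67_cutoff: float = 14.0
    her2_positive_levels: FrozenSet[Her2Score] = _DEFAULT_HER2_POSITIVE

    def __post_init__(self) -> None:
        if not 0.0 < self.ki67_cutoff < 100.0:
            raise ValueError(f"ki67_cutoff must lie in (0, 100): {self.ki67_cutoff}")
        levels = frozenset(self.her2_positive_levels)
        if Her2Score.MISSING in levels:
            raise ValueError("her2_positive_levels cannot contain MISSING")
        if levels:
            min_rank = min(s.rank for s in levels)
            upward = {s for s in Her2Score if s.is_definite and s.rank >= min_rank}
            if levels != upward:
                raise ValueError(
                    "her2_positive_levels must be upward-closed on the "
                    f"ordinal scale, got {sorted(s.value for s in levels)}"
                )
        object.__setattr__(self, "her2_positive_levels", levels)

    def her2_is_positive(self, score: Her2Score) -> Optional[bool]:
        if not score.is_definite:
            return None
        return score in self.her2_positive_levels

    def ki67_is_high(self, percent: Optional[float]) -> Optional[bool]:
        if percent is None:
            return None
        return percent >= self.ki67_cutoff


@dataclass(frozen=True)
class PhenotypeCall:
    """Classifier output: a definite subtype, an ambiguous set, or unknown."""

    kind: CallKind
    subtype: Optional[Subtype] = None
    candidates: FrozenSet[Subtype] = frozenset()

    def __post_init__(self) -> None:
        if self.kind is CallKind.DEFINITE and self.subtype is None:
            raise ValueError("definite call requires a subtype")
        if self.kind is CallKind.AMBIGUOUS and len(self.candidates) < 2:
            raise ValueError("ambiguous call requires >= 2 candidates")
        if self.kind is CallKind.UNKNOWN and (self.subtype or self.candidates):
            raise ValueError("unknown call carries no subtype or candidates")

    @property
    def is_definite(self) -> bool:
        return self.kind is not CallKind.UNKNOWN

    def label(self) -> str:
        if self.kind is CallKind.DEFINITE:
            return self.subtype.value
        if self.kind is CallKind.AMBIGUOUS:
            names = sorted(s.value for s in self.candidates)
            return " or ".join(names)
        return "Unknown"


UNKNOWN_CALL = PhenotypeCall(kind=CallKind.UNKNOWN)


def definite(subtype: Subtype) -> PhenotypeCall:
    return PhenotypeCall(kind=CallKind.DEFINITE, subtype=subtype)


def ambiguous(*subtypes: Subtype) -> PhenotypeCall:
    return PhenotypeCall(kind=CallKind.AMBIGUOUS, candidates=frozenset(subtypes))


def classify_complete(
    er: bool, pr: bool, her2: bool, ck56: bool, egfr: bool, ki67_high: bool
) -> Subtype:
    """Subtype for a fully observed panel; exactly one branch applies."""
    if er or pr:
        if her2:
            return Subtype.LUMINAL_B
        return Subtype.LUMINAL_B if ki67_high else Subtype.LUMINAL_A
    if her2:
        return Subtype.HER2_ENRICHED
    if ck56 or egfr:
        return Subtype.BASAL_LIKE
    return Subtype.UNCLASSIFIABLE


def _tristate(call: MarkerCall) -> Optional[bool]:
    if call is MarkerCall.MISSING:
        return None
    return call is MarkerCall.POSITIVE


def classify(panel: TmaPanel, rules: PhenotypeRules = PhenotypeRules()) -> PhenotypeCall:
    """Classify one TMA panel, resolving missing markers by enumeration."""
    er = _tristate(panel.er)
    pr = _tristate(panel.pr)
    her2 = rules.her2_is_positive(panel.her2)
    ck56 = _tristate(panel.ck56)
    egfr = _tristate(panel.egfr)
    ki67_high = rules.ki67_is_high(panel.ki67_percent)

    if er is None and pr is None:
        return UNKNOWN_CALL

    observed = (er, pr, her2, ck56, egfr, ki67_high)
    free = [i for i, v in enumerate(observed) if v is None]
    outcomes = set()
    for completion in itertools.product((False, True), repeat=len(free)):
        values = list(observed)
        for slot, val in zip(free, completion):
            values[slot] = val
        outcomes.add(classify_complete(*values))
    if len(outcomes) == 1:
        return definite(next(iter(outcomes)))
    if er is not None and pr is not None and er != pr:
        # Equivocal hormone-receptor pair plus a decisive missing marker:
        # reported as unknown rather than as a candidate set.
        return UNKNOWN_CALL
    return PhenotypeCall(kind=CallKind.AMBIGUOUS, candidates=frozenset(outcomes))


def classify_dataset(
    ds: StudyDataset, rules: PhenotypeRules = PhenotypeRules()
) -> Dict[Tuple[str, str], PhenotypeCall]:
    """One call per panel with any evaluable marker; fully-missing panels
    (the specimen contributed no tissue to that TMA) yield no entry."""
    return {
        (p.case_id, p.tma_id): classify(p, rules)
        for p in ds.panels
        if not p.is_fully_missing
    }


_PRINTED_LABELS = {
    "luminal a": Subtype.LUMINAL_A,
    "luminal b": Subtype.LUMINAL_B,
    "her2": Subtype.HER2_ENRICHED,
    "her 2": Subtype.HER2_ENRICHED,
    "basal-like": Subtype.BASAL_LIKE,
    "unclassifiable": Subtype.UNCLASSIFIABLE,
}


def matches_printed(call: PhenotypeCall, printed: str) -> bool:
    """Compare a call with a printed phenotype label.

    Printed "Unknown" and printed candidate sets ("X or Y") are treated
    as one undetermined family: "Unknown" matches any non-definite call,
    and "X or Y" matches the identical ambiguous set or an unknown call.
    """
    text = printed.strip().lower()
    if text in _PRINTED_LABELS:
        return (
            call.kind is CallKind.DEFINITE
            and call.subtype is _PRINTED_LABELS[text]
        )
    if text == "unknown":
        return call.kind in (CallKind.UNKNOWN, CallKind.AMBIGUOUS)
    if " or " in text:
        parts = [p.strip() for p in text.split(" or ")]
        try:
            expected = frozenset(_PRINTED_LABELS[p] for p in parts)
        except KeyError:
            raise ValueError(f"unrecognized printed phenotype {printed!r}") from None
        if call.kind is CallKind.AMBIGUOUS:
            return call.candidates == expected
        return call.kind is CallKind.UNKNOWN
    raise ValueError(f"unrecognized printed phenotype {printed!r}")
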