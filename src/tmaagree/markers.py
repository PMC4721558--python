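"""Typed immunostain results.

Binary stains (CK cocktail, ER, PR, CK 5/6, EGFR) are three-state
categorical calls: positive, negative, or missing (no evaluable tissue).
HER2 is scored on the ordinal immunohistochemistry scale 0/1+/2+/3+; the
reference data print only "-", "2+" and "3+", but the full scale is
representable.  Ki67 is a percent-positive-cells score in [0, 100].
"""

from __future__ import annotations

import enum
from typing import Optional


class MarkerCall(enum.Enum):
    """Three-state call for a binary immunostain."""

    POSITIVE = "pos"
    NEGATIVE = "neg"
    MISSING = "NA"

    @property
    def is_definite(self) -> bool:
        return self is not MarkerCall.MISSING

    def __bool__(self) -> bool:  # guard against accidental truthiness
        raise TypeError("MarkerCall has no truth value; compare explicitly")


class Her2Score(enum.Enum):
    """Ordinal HER2 immunostain score.

    ``rank`` orders the definite levels negative < 1+ < 2+ < 3+; MISSING
    has no rank and never participates in ordinal comparisons.
    """

    NEGATIVE = "neg"
    ONE_PLUS = "1+"
    TWO_PLUS = "2+"
    THREE_PLUS = "3+"
    MISSING = "NA"

    @property
    def is_definite(self) -> bool:
        return self is not Her2Score.MISSING

    @property
    def rank(self) -> int:
        if self is Her2Score.MISSING:
            raise ValueError("missing HER2 score has no ordinal rank")
        return _HER2_RANK[self]


_HER2_RANK = {
    Her2Score.NEGATIVE: 0,
    Her2Score.ONE_PLUS: 1,
    Her2Score.TWO_PLUS: 2,
    Her2Score.THREE_PLUS: 3,
}

#: HER2 levels counted positive when pairing duplicate-TMA results for the
#: chance-corrected agreement statistics (2+ and 3+ both count positive).
HER2_RELIABILITY_POSITIVE = frozenset({Her2Score.TWO_PLUS, Her2Score.THREE_PLUS})


def validate_ki67(percent: Optional[float]) -> Optional[float]:
    """Validate a Ki67 percent-positive score; ``None`` encodes missing."""
    if percent is None:
        return None
    value = float(percent)
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"Ki67 percent out of range [0, 100]: {value!r}")
    return value


def parse_marker(text: str) -> MarkerCall:
    """Parse a binary marker cell ('pos', 'neg', 'NA'/'', or '+'/'-')."""
    cleaned = text.strip()
    aliases = {
        "pos": MarkerCall.POSITIVE,
        "+": MarkerCall.POSITIVE,
        "neg": MarkerCall.NEGATIVE,
        "-": MarkerCall.NEGATIVE,
        "−": MarkerCall.NEGATIVE,
        "na": MarkerCall.MISSING,
        "": MarkerCall.MISSING,
    }
    try:
        return aliases[cleaned.lower() if cleaned.lower() == "na" else cleaned]
    except KeyError:
        raise ValueError(f"unrecognized marker call: {text!r}") from None


def parse_her2(text: str) -> Her2Score:
    cleaned = text.strip()
    aliases = {
        "neg": Her2Score.NEGATIVE,
        "-": Her2Score.NEGATIVE,
        "−": Her2Score.NEGATIVE,
        "0": Her2Score.NEGATIVE,
        "1+": Her2Score.ONE_PLUS,
        "2+": Her2Score.TWO_PLUS,
        "3+": Her2Score.THREE_PLUS,
        "na": Her2Score.MISSING,
        "": Her2Score.MISSING,
    }
    try:
        return aliases[cleaned.lower() if cleaned.lower() == "na" else cleaned]
    except KeyError:
        raise ValueError(f"unrecognized HER2 score: {text!r}") from None
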