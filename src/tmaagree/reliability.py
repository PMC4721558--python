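"""Test-retest agreement between duplicate TMAs.

Pairs one call per case from TMA1 and TMA2 and summarizes agreement two
ways, as in the reference study:

* percent concordance over *all* cases, where a pair counts discordant
  only when both calls are definite and differ (a missing side never
  creates discordance), rounded half-up to integer percent; and
* unweighted Cohen's kappa over *complete* pairs only, with the
  large-sample (Fleiss-Cohen-Everitt) standard error and either an
  asymptotic normal confidence interval clipped to [-1, 1] or a
  case-resampled bootstrap percentile interval.

HER2 is compared on the reported stain categories for concordance
(2+ vs negative differs) but dichotomized with 2+ and 3+ positive for
kappa; Ki67 is dichotomized at the classifier cutoff (default 14%,
boundary high); phenotype calls treat unknown as missing and an
ambiguous candidate set as a definite category of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import StudyDataset, TmaPanel
from .markers import HER2_RELIABILITY_POSITIVE, Her2Score, MarkerCall
from .phenotype import PhenotypeRules, classify_dataset

BINARY_TARGETS = ("ck_cocktail", "er", "pr", "ck56", "egfr")
ALL_TARGETS = ("ck_cocktail", "er", "pr", "her2", "ck56", "egfr", "ki67", "phenotype")


@dataclass(frozen=True)
class PairSet:
    """Per-case (TMA1, TMA2) call pairs for one target; ``None`` = missing."""

    label: str
    pairs: Tuple[Tuple[str, Optional[str], Optional[str]], ...]
    policy: str

    @property
    def n_total_cases(self) -> int:
        return len(self.pairs)

    @property
    def n_complete(self) -> int:
        return sum(1 for _, a, b in self.pairs if a is not None and b is not None)

    def complete_pairs(self) -> List[Tuple[str, str, str]]:
        return [(c, a, b) for c, a, b in self.pairs if a is not None and b is not None]


@dataclass(frozen=True)
class Concordance:
    label: str
    percent: int
    raw: float
    n_discordant: int
    n_total_cases: int


@dataclass(frozen=True)
class AgreementResult:
    """Cohen's kappa on complete pairs, with optional confidence bounds."""

    label: str
    n_pairs: int
    categories: Tuple[str, ...]
    p_observed: float
    p_expected: float
    kappa: Optional[float]
    se: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    ci_method: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.kappa is not None


def _binary_value(call: MarkerCall) -> Optional[str]:
    if call is MarkerCall.MISSING:
        return None
    return call.value


def _her2_category(score: Her2Score) -> Optional[str]:
    return score.value if score.is_definite else None


def _her2_binary(score: Her2Score) -> Optional[str]:
    if not score.is_definite:
        return None
    return "pos" if score in HER2_RELIABILITY_POSITIVE else "neg"


def _ki67_value(percent: Optional[float], cutoff: float) -> Optional[str]:
    if percent is None:
        return None
    return "high" if percent >= cutoff else "low"


def build_pairs(
    ds: StudyDataset,
    target: str,
    rules: PhenotypeRules = PhenotypeRules(),
    coding: str = "category",
) -> PairSet:
    """Assemble one call pair per case for ``target``.

    ``coding`` is ``"category"`` (reported categories: pos/neg for binary
    stains, the stain level for HER2, high/low for Ki67, the call label
    for phenotype) or ``"reliability-binary"`` (HER2 only: 2+/3+ -> pos).
    """
    if target not in ALL_TARGETS:
        raise ValueError(f"unknown target {target!r}; expected one of {ALL_TARGETS}")
    if coding not in ("category", "reliability-binary"):
        raise ValueError(f"unknown coding {coding!r}")
    if coding == "reliability-binary" and target != "her2":
        raise ValueError("reliability-binary coding applies to HER2 only")

    calls = classify_dataset(ds, rules) if target == "phenotype" else None

    def value(panel: Optional[TmaPanel], case_id: str, tma_id: str) -> Optional[str]:
        if target == "phenotype":
            call = calls.get((case_id, tma_id))
            if call is None or not call.is_definite:
                return None
            return call.label()
        if panel is None:
            return None
        if target == "her2":
            coder = _her2_binary if coding == "reliability-binary" else _her2_category
            return coder(panel.her2)
        if target == "ki67":
            return _ki67_value(panel.ki67_percent, rules.ki67_cutoff)
        return _binary_value(getattr(panel, target))

    pairs = tuple(
        (
            case.case_id,
            value(ds.panel(case.case_id, "TMA1"), case.case_id, "TMA1"),
            value(ds.panel(case.case_id, "TMA2"), case.case_id, "TMA2"),
        )
        for case in ds.cases
    )
    policy_bits = [f"coding={coding}"]
    if target == "ki67":
        policy_bits.append(f"cutoff={rules.ki67_cutoff}")
    if target == "phenotype":
        policy_bits.append("unknown=missing, ambiguous=distinct-category")
    return PairSet(label=target, pairs=pairs, policy="; ".join(policy_bits))


def percent_concordance(ps: PairSet) -> Concordance:
    """Concordance over all cases; discordance needs two definite, differing calls."""
    if ps.n_total_cases == 0:
        raise ValueError("percent concordance undefined for an empty pair set")
    n_disc = sum(
        1 for _, a, b in ps.pairs if a is not None and b is not None and a != b
    )
    raw = 100.0 * (ps.n_total_cases - n_disc) / ps.n_total_cases
    percent = int(Decimal(raw).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    return Concordance(
        label=ps.label,
        percent=percent,
        raw=raw,
        n_discordant=n_disc,
        n_total_cases=ps.n_total_cases,
    )


def contingency_table(ps: PairSet) -> Tuple[Tuple[str, ...], np.ndarray]:
    """k x k counts over complete pairs; rows index TMA1, columns TMA2."""
    complete = ps.complete_pairs()
    categories = tuple(sorted({a for _, a, _ in complete} | {b for _, _, b in complete}))
    index = {c: i for i, c in enumerate(categories)}
    counts = np.zeros((len(categories), len(categories)), dtype=int)
    for _, a, b in complete:
        counts[index[a], index[b]] += 1
    return categories, counts


def cohen_kappa(
    counts: np.ndarray,
    categories: Optional[Sequence[str]] = None,
    label: str = "",
) -> AgreementResult:
    """Unweighted Cohen's kappa with the Fleiss-Cohen-Everitt standard error.

    ``counts[i, j]`` is the number of complete pairs rated category ``i``
    by the first determination and ``j`` by the second.  When all mass
    sits in one cell the expected agreement is 1 and kappa is undefined
    (returned as ``None``).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError(f"counts must be square, got shape {counts.shape}")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("empty contingency table")
    cats = tuple(categories) if categories is not None else tuple(
        str(i) for i in range(counts.shape[0])
    )
    p = counts / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(row @ col)
    if 1.0 - pe < 1e-12:
        return AgreementResult(
            label=label, n_pairs=int(n), categories=cats,
            p_observed=po, p_expected=pe, kappa=None,
        )
    kappa = (po - pe) / (1.0 - pe)
    # Large-sample variance of kappa-hat (Fleiss, Cohen & Everitt 1969).
    diag = np.diag(p)
    term1 = float(np.sum(diag * ((1 - pe) - (row + col) * (1 - po)) ** 2))
    cross = (col[:, None] + row[None, :]) ** 2  # (p_.i + p_j.)^2 for cell (i, j)
    off = p * cross
    np.fill_diagonal(off, 0.0)
    term2 = float((1 - po) ** 2 * off.sum())
    term3 = (po * pe - 2 * pe + po) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    return AgreementResult(
        label=label, n_pairs=int(n), categories=cats,
        p_observed=po, p_expected=pe, kappa=float(kappa), se=se,
    )


def kappa_from_pairs(ps: PairSet) -> AgreementResult:
    if ps.n_complete == 0:
        return AgreementResult(
            label=ps.label, n_pairs=0, categories=(),
            p_observed=float("nan"), p_expected=float("nan"), kappa=None,
        )
    categories, counts = contingency_table(ps)
    return cohen_kappa(counts, categories, label=ps.label)


def kappa_ci(
    ps: PairSet,
    method: str = "asymptotic",
    level: float = 0.95,
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> AgreementResult:
    """Kappa plus a confidence interval, bounds clipped to [-1, 1].

    ``asymptotic`` uses kappa +/- z * SE; ``bootstrap`` resamples complete
    pairs (cases) with replacement and takes the percentile interval,
    dropping resamples on which kappa is undefined.
    """
    result = kappa_from_pairs(ps)
    if not result.defined:
        return result
    if method == "asymptotic":
        z = stats.norm.ppf(0.5 + level / 2.0)
        low = max(result.kappa - z * result.se, -1.0)
        high = min(result.kappa + z * result.se, 1.0)
        return replace(result, ci_low=low, ci_high=high, ci_method="asymptotic")
    if method == "bootstrap":
        if n_boot < 100:
            raise ValueError("bootstrap requires n_boot >= 100")
        rng = np.random.default_rng(seed)
        complete = ps.complete_pairs()
        cat_index = {c: i for i, c in enumerate(result.categories)}
        k = len(result.categories)
        idx = np.array([(cat_index[a], cat_index[b]) for _, a, b in complete])
        samples: List[float] = []
        for _ in range(n_boot):
            take = rng.integers(0, len(complete), size=len(complete))
            counts = np.zeros((k, k))
            np.add.at(counts, (idx[take, 0], idx[take, 1]), 1)
            boot = cohen_kappa(counts, result.categories)
            if boot.defined:
                samples.append(boot.kappa)
        alpha = (1.0 - level) / 2.0
        low, high = np.quantile(samples, [alpha, 1.0 - alpha])
        return replace(
            result,
            ci_low=float(max(low, -1.0)),
            ci_high=float(min(high, 1.0)),
            ci_method=f"bootstrap(n={n_boot})",
        )
    raise ValueError(f"unknown CI method {method!r}")


def reliability_report(
    ds: StudyDataset,
    rules: PhenotypeRules = PhenotypeRules(),
    ci_method: str = "asymptotic",
    level: float = 0.95,
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """One row per target with concordance, kappa, CI and conventions.

    HER2 concordance compares reported stain categories while HER2 kappa
    uses the 2+/3+-positive dichotomy; both conventions are recorded in
    the ``policy`` column.
    """
    rows = []
    for target in ALL_TARGETS:
        ps = build_pairs(ds, target, rules)
        conc = percent_concordance(ps)
        if target == "her2":
            kp = build_pairs(ds, target, rules, coding="reliability-binary")
            policy = f"concordance: {ps.policy}; kappa: {kp.policy}"
        else:
            kp = ps
            policy = ps.policy
        ar = kappa_ci(kp, method=ci_method, level=level, n_boot=n_boot, seed=seed)
        rows.append(
            {
                "target": target,
                "n_cases": ps.n_total_cases,
                "n_complete_kappa": ar.n_pairs,
                "n_discordant": conc.n_discordant,
                "concordance_pct": conc.percent,
                "concordance_raw": conc.raw,
                "kappa": ar.kappa,
                "se": ar.se,
                "ci_low": ar.ci_low,
                "ci_high": ar.ci_high,
                "ci_method": ar.ci_method,
                "policy": policy,
            }
        )
    return pd.DataFrame(rows)
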