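"""Synthetic TMA-study generator.

Emulates the data-producing process of the archival feasibility design:
cases are sampled per decade stratum, pathology reports and tumor blocks
are retrieved with configurable success probabilities, a fixed number of
cases per stratum is subsampled for analysis, and each analyzed case
contributes three cores to each of two duplicate TMAs.  Staining noise
is modeled with a shared latent marker state per case driving both TMAs:
binary stains via per-core sensitivity/specificity, HER2 via a latent
amplified/not-amplified state with per-core ordinal confusion
distributions, Ki67 via a right-skewed latent per-case mean with
multiplicative per-core dispersion, and tissue loss via a per-core
dropout probability.  The error mechanism is invented for testing; the
reference study describes none.

A single root seed is expanded with ``numpy.random.SeedSequence`` into
per-stage child generators, so each stage is individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .aggregation import CoreScore, aggregate_panel
from .dataset import (
    DECADE_LABELS,
    DECADE_STRATA,
    CaseRecord,
    StudyDataset,
    TmaPanel,
)
from .markers import Her2Score, MarkerCall
from .reliability import build_pairs, kappa_from_pairs, percent_concordance

HER2_LEVELS = (
    Her2Score.NEGATIVE,
    Her2Score.ONE_PLUS,
    Her2Score.TWO_PLUS,
    Her2Score.THREE_PLUS,
)

#: Default latent prevalences, set to the positivity the reference study
#: reports: ~80% ER+, 60% PR+, 20-40% HER2+ (0.3 used), 13% CK 5/6+,
#: 7% EGFR+; CK cocktail models antigen preservation (28/30 preserved).
DEFAULT_PREVALENCE: Dict[str, float] = {
    "ck_cocktail": 28 / 30,
    "er": 0.80,
    "pr": 0.60,
    "her2": 0.30,
    "ck56": 0.13,
    "egfr": 0.07,
}


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters for the generator.

    The sampling defaults mirror the reference design: 10 cases sampled
    per each of 6 decade strata, report retrieval probability 55/60 and
    block retrieval 50/55 given a report (the study's realized rates),
    5 cases per stratum analyzed, 3 cores per specimen per TMA.  The
    Ki67 latent mean is log-normal with median 5% and log-sd 0.80,
    which puts ~10% of cases at or above the 14% cutoff, matching the
    86-90% low-Ki67 fraction observed.
    """

    n_sampled_per_stratum: int = 10
    n_analyzed_per_stratum: int = 5
    strata: Tuple[str, ...] = DECADE_LABELS
    p_report: float = 55 / 60
    p_block_given_report: float = 50 / 55
    cores_per_panel: int = 3
    marker_prevalence: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    core_sensitivity: float = 0.95
    core_specificity: float = 0.97
    core_dropout: float = 0.05
    ki67_log_median: float = math.log(5.0)
    ki67_log_sd: float = 0.80
    ki67_core_log_sd: float = 0.25
    her2_core_dist_pos: Tuple[float, ...] = (0.01, 0.02, 0.07, 0.90)
    her2_core_dist_neg: Tuple[float, ...] = (0.85, 0.08, 0.06, 0.01)

    def __post_init__(self) -> None:
        for name in ("p_report", "p_block_given_report", "core_sensitivity",
                     "core_specificity", "core_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for marker, prev in self.marker_prevalence.items():
            if not 0.0 <= prev <= 1.0:
                raise ValueError(f"prevalence for {marker!r} out of [0, 1]: {prev}")
        if self.cores_per_panel < 1:
            raise ValueError("cores_per_panel must be >= 1")
        if self.n_analyzed_per_stratum > self.n_sampled_per_stratum:
            raise ValueError("cannot analyze more cases than sampled per stratum")
        for dist_name in ("her2_core_dist_pos", "her2_core_dist_neg"):
            dist = getattr(self, dist_name)
            if len(dist) != 4 or abs(sum(dist) - 1.0) > 1e-9 or min(dist) < 0:
                raise ValueError(f"{dist_name} must be 4 probabilities summing to 1")


@dataclass(frozen=True)
class CaseTruth:
    """Latent state of one sampled case (shared by both TMAs)."""

    case_id: str
    diagnosis_year: int
    decade: str
    grade: int
    histology: str
    marker_state: Dict[str, bool]  # binary stains incl. CK cocktail
    her2_positive: bool
    ki67_mean: float


@dataclass(frozen=True)
class RetrievalRecord:
    case_id: str
    report_located: bool
    block_located: bool
    analyzed: bool


@dataclass(frozen=True)
class RetrievalLog:
    records: Tuple[RetrievalRecord, ...]
    shortfalls: Dict[str, int]  # stratum -> unmet quota

    @property
    def n_sampled(self) -> int:
        return len(self.records)

    @property
    def n_report(self) -> int:
        return sum(r.report_located for r in self.records)

    @property
    def n_block(self) -> int:
        return sum(r.block_located for r in self.records)

    @property
    def analyzed_ids(self) -> List[str]:
        return [r.case_id for r in self.records if r.analyzed]


@dataclass
class SimStudy:
    config: SimConfig
    truths: List[CaseTruth]
    retrieval: RetrievalLog
    cores: List[CoreScore]
    dataset: StudyDataset


Seed = Optional[object]  # int or numpy SeedSequence


def _stage_rngs(seed: Seed, n: int) -> List[np.random.Generator]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def simulate_truth(cfg: SimConfig, rng: np.random.Generator) -> List[CaseTruth]:
    """Draw latent states for every sampled case, stratified by decade."""
    bounds = dict(zip(DECADE_LABELS, DECADE_STRATA))
    truths: List[CaseTruth] = []
    for s_idx, stratum in enumerate(cfg.strata, start=1):
        lo, hi = bounds[stratum]
        for k in range(cfg.n_sampled_per_stratum):
            case_id = f"{s_idx}-{(s_idx - 1) * cfg.n_sampled_per_stratum + k + 1}"
            state = {
                m: bool(rng.random() < p) for m, p in cfg.marker_prevalence.items()
                if m != "her2"
            }
            her2_pos = bool(rng.random() < cfg.marker_prevalence.get("her2", 0.0))
            ki67 = float(
                np.clip(rng.lognormal(cfg.ki67_log_median, cfg.ki67_log_sd), 0.0, 100.0)
            )
            truths.append(
                CaseTruth(
                    case_id=case_id,
                    diagnosis_year=int(rng.integers(lo, hi + 1)),
                    decade=stratum,
                    grade=int(rng.integers(1, 4)),
                    histology="IDC",
                    marker_state=state,
                    her2_positive=her2_pos,
                    ki67_mean=ki67,
                )
            )
    return truths


def simulate_retrieval(
    cfg: SimConfig, truths: Sequence[CaseTruth], rng: np.random.Generator
) -> RetrievalLog:
    """Two-stage retrieval plus stratified subsampling of analyzed cases.

    A stratum that cannot fill its quota is recorded in ``shortfalls``
    (deficit count) rather than silently under-filled.
    """
    report = {t.case_id: bool(rng.random() < cfg.p_report) for t in truths}
    block = {
        t.case_id: report[t.case_id] and bool(rng.random() < cfg.p_block_given_report)
        for t in truths
    }
    analyzed: set = set()
    shortfalls: Dict[str, int] = {}
    for stratum in cfg.strata:
        eligible = [t.case_id for t in truths if t.decade == stratum and block[t.case_id]]
        quota = cfg.n_analyzed_per_stratum
        if len(eligible) < quota:
            shortfalls[stratum] = quota - len(eligible)
            chosen = eligible
        else:
            chosen = list(rng.choice(eligible, size=quota, replace=False))
        analyzed.update(chosen)
    records = tuple(
        RetrievalRecord(
            case_id=t.case_id,
            report_located=report[t.case_id],
            block_located=block[t.case_id],
            analyzed=t.case_id in analyzed,
        )
        for t in truths
    )
    return RetrievalLog(records=records, shortfalls=shortfalls)


def _simulate_binary_core(
    latent: bool, cfg: SimConfig, rng: np.random.Generator
) -> MarkerCall:
    if latent:
        return MarkerCall.POSITIVE if rng.random() < cfg.core_sensitivity else MarkerCall.NEGATIVE
    return MarkerCall.NEGATIVE if rng.random() < cfg.core_specificity else MarkerCall.POSITIVE


def simulate_cores(
    cfg: SimConfig, truth: CaseTruth, rng: np.random.Generator
) -> List[CoreScore]:
    """Core-level results for one case on both TMAs."""
    cores: List[CoreScore] = []
    for tma_id in ("TMA1", "TMA2"):
        for core_index in range(1, cfg.cores_per_panel + 1):
            dropped = bool(rng.random() < cfg.core_dropout)
            for marker, latent in truth.marker_state.items():
                result: object
                if dropped:
                    result = MarkerCall.MISSING
                else:
                    result = _simulate_binary_core(latent, cfg, rng)
                cores.append(
                    CoreScore(truth.case_id, tma_id, core_index, marker,
                              result, tissue_present=not dropped)
                )
            if dropped:
                her2_result: Her2Score = Her2Score.MISSING
                ki67_result: Optional[float] = None
            else:
                dist = (
                    cfg.her2_core_dist_pos if truth.her2_positive
                    else cfg.her2_core_dist_neg
                )
                her2_result = HER2_LEVELS[int(rng.choice(4, p=dist))]
                ki67_result = float(
                    np.clip(
                        truth.ki67_mean * math.exp(rng.normal(0.0, cfg.ki67_core_log_sd)),
                        0.0,
                        100.0,
                    )
                )
            cores.append(
                CoreScore(truth.case_id, tma_id, core_index, "her2",
                          her2_result, tissue_present=not dropped)
            )
            cores.append(
                CoreScore(truth.case_id, tma_id, core_index, "ki67",
                          ki67_result, tissue_present=not dropped)
            )
    return cores


def simulate_study(cfg: SimConfig, seed: Seed = None) -> SimStudy:
    """Run the full generative chain and aggregate to a study dataset."""
    truth_rng, retrieval_rng, core_rng = _stage_rngs(seed, 3)
    truths = simulate_truth(cfg, truth_rng)
    retrieval = simulate_retrieval(cfg, truths, retrieval_rng)
    analyzed = set(retrieval.analyzed_ids)
    truth_by_id = {t.case_id: t for t in truths}
    cores: List[CoreScore] = []
    panels: List[TmaPanel] = []
    cases: List[CaseRecord] = []
    for case_id in sorted(analyzed, key=lambda c: tuple(map(int, c.split("-")))):
        truth = truth_by_id[case_id]
        cases.append(
            CaseRecord(case_id, truth.diagnosis_year, truth.histology, truth.grade)
        )
        case_cores = simulate_cores(cfg, truth, core_rng)
        cores.extend(case_cores)
        for tma_id in ("TMA1", "TMA2"):
            panels.append(
                aggregate_panel(
                    case_id, tma_id,
                    [c for c in case_cores if c.tma_id == tma_id],
                )
            )
    dataset = StudyDataset(cases=cases, panels=panels)
    return SimStudy(config=cfg, truths=truths, retrieval=retrieval,
                    cores=cores, dataset=dataset)


def truth_frame(study: SimStudy) -> pd.DataFrame:
    rows = []
    for t in study.truths:
        row = {
            "case_id": t.case_id,
            "year": t.diagnosis_year,
            "decade": t.decade,
            "grade": t.grade,
            "her2_positive": t.her2_positive,
            "ki67_mean": t.ki67_mean,
        }
        row.update({m: v for m, v in t.marker_state.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def retrieval_frame(study: SimStudy) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "report_located": r.report_located,
                "block_located": r.block_located,
                "analyzed": r.analyzed,
            }
            for r in study.retrieval.records
        ]
    )


def cores_frame(study: SimStudy) -> pd.DataFrame:
    def encode(c: CoreScore) -> str:
        if isinstance(c.result, (MarkerCall, Her2Score)):
            return c.result.value
        if c.result is None:
            return "NA"
        return format(c.result, "g")

    return pd.DataFrame(
        [
            {
                "case_id": c.case_id,
                "tma_id": c.tma_id,
                "core_index": c.core_index,
                "marker": c.marker,
                "result": encode(c),
                "tissue_present": c.tissue_present,
            }
            for c in study.cores
        ]
    )


def estimate_core_operating_characteristics(
    study: SimStudy,
) -> Tuple[float, float]:
    """Empirical per-core (sensitivity, specificity) of the binary stains,
    pooled across markers, against the generating latent states."""
    truth_by_id = {t.case_id: t for t in study.truths}
    tp = fn = tn = fp = 0
    for core in study.cores:
        if not core.tissue_present or not isinstance(core.result, MarkerCall):
            continue
        latent = truth_by_id[core.case_id].marker_state[core.marker]
        pos = core.result is MarkerCall.POSITIVE
        if latent:
            tp += pos
            fn += not pos
        else:
            fp += pos
            tn += not pos
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("cannot estimate operating characteristics: a latent "
                         "class is empty")
    return tp / (tp + fn), tn / (tn + fp)


def kappa_prevalence_sweep(
    cfg: SimConfig,
    prevalences: Sequence[float],
    n_reps: int = 20,
    seed: Optional[int] = None,
    marker: str = "er",
) -> pd.DataFrame:
    """Mean concordance and kappa for one binary stain across prevalences.

    Noise parameters are held fixed; only the latent prevalence of
    ``marker`` varies, which isolates the prevalence effect on chance
    agreement.  Replicates on which kappa is undefined (a single realized
    category on both TMAs) are excluded from the kappa mean and counted
    in ``n_kappa_defined``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seeds = np.random.SeedSequence(seed).spawn(len(prevalences))
    rows = []
    for prev, prev_seed in zip(prevalences, seeds):
        prevalence = dict(cfg.marker_prevalence)
        prevalence[marker] = float(prev)
        sub_cfg = replace(cfg, marker_prevalence=prevalence)
        rep_seeds = prev_seed.spawn(n_reps)
        concordances: List[float] = []
        kappas: List[float] = []
        for rep_seed in rep_seeds:
            study = simulate_study(sub_cfg, seed=rep_seed)
            ps = build_pairs(study.dataset, marker)
            concordances.append(percent_concordance(ps).raw)
            ar = kappa_from_pairs(ps)
            if ar.defined:
                kappas.append(ar.kappa)
        rows.append(
            {
                "prevalence": float(prev),
                "mean_concordance": float(np.mean(concordances)),
                "mean_kappa": float(np.mean(kappas)) if kappas else float("nan"),
                "n_kappa_defined": len(kappas),
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)
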