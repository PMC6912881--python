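"""Model evaluation: split plans, AUC, TSS, thresholds, and the selection gate.

Each learner is calibrated on a random 75% of the survey sites and tested on
the held-out 25%; the split is repeated (default 10 replicates) to average
out split luck.  Discrimination is measured with the rank-based AUC
(Mann-Whitney statistic with midranks for ties) and the true skill statistic
TSS = sensitivity + specificity - 1, evaluated at the threshold that
maximises sensitivity + specificity.  Models enter the ensemble only if they
clear AUC > 0.8 and TSS > 0.45 on the held-out data (strict inequalities).

AUC quality classes: fair = [0.7, 0.8), good = [0.8, 1]; TSS quality:
fair = [0.4, 0.6), good = [0.6, 1]; anything lower is "poor".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "SplitPlan",
    "EvalRecord",
    "SelectionRule",
    "split_data",
    "auc_score",
    "optimal_threshold",
    "evaluate_model",
    "select_models",
    "records_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitPlan:
    """One calibration/test partition of n sites."""

    replicate: int
    fraction: float
    calibration: np.ndarray
    test: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return len(self.calibration) + len(self.test)


@dataclass
class EvalRecord:
    """Held-out performance of one fitted model (algorithm x replicate)."""

    species: str
    algorithm: str
    replicate: int
    auc: float
    tss: float
    threshold: float
    sensitivity: float
    specificity: float
    auc_quality: str = field(default="")
    tss_quality: str = field(default="")
    selected: bool = False


@dataclass(frozen=True)
class SelectionRule:
    """Ensemble admission gate (strict inequalities)."""

    min_auc: float = 0.8
    min_tss: float = 0.45

    def __post_init__(self) -> None:
        if not (0 <= self.min_auc <= 1 and 0 <= self.min_tss <= 1):
            raise ValueError("selection bounds must lie in [0, 1]")

    def passes(self, record: EvalRecord) -> bool:
        return record.auc > self.min_auc and record.tss > self.min_tss


def split_data(n: int, fraction: float = 0.75, replicate: int = 1, seed: int = 0) -> SplitPlan:
    """Uniform random calibration/test split.

    Replicate r draws from a derived seed ``seed + r`` so that plans are
    reproducible and mutually independent; ``|calibration| = round(fraction*n)``.
    """
    if not 0 < fraction < 1:
        raise ValueError("calibration fraction must be in (0, 1)")
    if n < 8:
        raise ValueError("need at least 8 sites to split")
    rng = np.random.default_rng(seed + replicate)
    perm = rng.permutation(n)
    n_cal = round(fraction * n)
    return SplitPlan(
        replicate=replicate,
        fraction=fraction,
        calibration=np.sort(perm[:n_cal]),
        test=np.sort(perm[n_cal:]),
        seed=seed,
    )


def auc_score(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with midranks for tied scores.

    Returns NaN (with a warning) when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        logger.warning("AUC undefined with a single class; returning NaN")
        return float("nan")
    ranks = rankdata(scores, method="average")
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores, plus below-min and
    above-max cuts (an all-present and an all-absent classifier)."""
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate(([uniq[0]], mids, [uniq[-1] + 1.0]))


def optimal_threshold(scores, labels) -> tuple[float, float, float, float]:
    """Threshold maximising sensitivity + specificity.

    Classification rule: predict presence iff ``score >= tau``.  Ties on the
    objective break toward the smallest threshold (favours sensitivity).
    Returns ``(tau, sensitivity, specificity, tss)`` at the optimum.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n1 = (labels == 1).sum()
    n0 = (labels == 0).sum()
    if n1 == 0 or n0 == 0:
        logger.warning("threshold undefined with a single class; returning NaN")
        return float("nan"), float("nan"), float("nan"), float("nan")
    taus = _candidate_thresholds(scores)
    pred = scores[None, :] >= taus[:, None]
    sens = (pred & (labels == 1)).sum(axis=1) / n1
    spec = (~pred & (labels == 0)).sum(axis=1) / n0
    objective = sens + spec
    best = int(np.argmax(objective))  # argmax keeps the first (smallest tau)
    return float(taus[best]), float(sens[best]), float(spec[best]), float(objective[best] - 1.0)


def _auc_quality(auc: float) -> str:
    if math.isnan(auc):
        return "undefined"
    if auc >= 0.8:
        return "good"
    if auc >= 0.7:
        return "fair"
    return "poor"


def _tss_quality(tss: float) -> str:
    if math.isnan(tss):
        return "undefined"
    if tss >= 0.6:
        return "good"
    if tss >= 0.4:
        return "fair"
    return "poor"


def evaluate_model(
    model,
    test_design: pd.DataFrame,
    test_labels,
    species: str = "",
    algorithm: str = "",
    replicate: int = 0,
) -> EvalRecord:
    """Score a fitted model on held-out rows only."""
    scores = model.predict_suitability(test_design)
    labels = np.asarray(test_labels, dtype=float)
    auc = auc_score(scores, labels)
    tau, sens, spec, tss = optimal_threshold(scores, labels)
    return EvalRecord(
        species=species,
        algorithm=algorithm,
        replicate=replicate,
        auc=auc,
        tss=tss,
        threshold=tau,
        sensitivity=sens,
        specificity=spec,
        auc_quality=_auc_quality(auc),
        tss_quality=_tss_quality(tss),
    )


def select_models(
    records: Sequence[EvalRecord], rule: SelectionRule = SelectionRule()
) -> tuple[list[EvalRecord], int]:
    """Apply the admission gate; returns (selected records, percent selected).

    ``percent_selected`` is ``100 * |selected| / |records|`` rounded to the
    nearest integer.  An empty selection is legal; downstream consensus then
    reports "no consensus possible".
    """
    selected = []
    for rec in records:
        rec.selected = (not math.isnan(rec.auc)) and (not math.isnan(rec.tss)) and rule.passes(rec)
        if rec.selected:
            selected.append(rec)
    percent = round(100.0 * len(selected) / len(records)) if records else 0
    return selected, percent


def records_to_frame(records: Sequence[EvalRecord]) -> pd.DataFrame:
    """Evaluation table mirroring the published per-model summary columns."""
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "algorithm": r.algorithm,
                "replicate": r.replicate,
                "auc": r.auc,
                "tss": r.tss,
                "threshold": r.threshold,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "auc_quality": r.auc_quality,
                "tss_quality": r.tss_quality,
                "selected": r.selected,
            }
            for r in records
        ]
    )
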