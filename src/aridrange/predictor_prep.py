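"""Collinearity screening of candidate predictors.

Strongly collinear predictors destabilise suitability models, so before any
model is calibrated the candidate set is screened with a pairwise Pearson
threshold: only one variable from any pair with ``|r| >= 0.70`` is retained.
Which member of a correlated pair survives is an ecological judgement, not an
algorithmic one, so it enters as an explicit priority ordering: variables are
scanned in priority order and accepted iff they clear the threshold against
every variable already accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationMatrix",
    "ScreeningResult",
    "correlation_matrix",
    "collinearity_filter",
    "DEFAULT_CORR_THRESHOLD",
]

logger = logging.getLogger(__name__)

DEFAULT_CORR_THRESHOLD = 0.70


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson r over sites (pairwise-complete observations)."""

    variables: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        p = len(self.variables)
        if self.r.shape != (p, p):
            raise ValueError("correlation matrix shape must match variable count")

    def get(self, a: str, b: str) -> float:
        i, j = self.variables.index(a), self.variables.index(b)
        return float(self.r[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variables, columns=self.variables)


@dataclass
class ScreeningResult:
    kept: list[str]
    dropped: list[tuple[str, str, float]] = field(default_factory=list)
    threshold: float = DEFAULT_CORR_THRESHOLD

    def report(self) -> pd.DataFrame:
        rows = [(v, "kept", "", np.nan) for v in self.kept]
        rows += [(v, "dropped", partner, absr) for v, partner, absr in self.dropped]
        return pd.DataFrame(rows, columns=["variable", "status", "partner", "abs_r"])

    def write_report(self, path: str | Path) -> None:
        self.report().to_csv(path, index=False)


def correlation_matrix(design: pd.DataFrame, variables: Sequence[str] | None = None) -> CorrelationMatrix:
    """Pearson correlations between predictor columns of a design table.

    Pairwise-complete; a zero-variance variable has undefined correlations,
    recorded as 0 with a warning.
    """
    if variables is None:
        variables = [
            c for c in design.columns
            if c not in ("site_id", "x", "y", "species", "presence")
            and pd.api.types.is_numeric_dtype(design[c])
        ]
    variables = list(variables)
    sub = design[variables]
    if len(sub.dropna()) < 3:
        raise ValueError("need at least 3 complete sites to correlate")
    r = sub.corr(method="pearson", min_periods=3).to_numpy()
    degenerate = [v for v, std in sub.std().items() if std == 0]
    if degenerate:
        logger.warning(
            "zero-variance variable(s) %s: correlations undefined, recorded as 0",
            degenerate,
        )
    bad = ~np.isfinite(r)
    r[bad] = 0.0
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(variables, r)


def collinearity_filter(
    corr: CorrelationMatrix,
    threshold: float = DEFAULT_CORR_THRESHOLD,
    priority: Sequence[str] | None = None,
) -> ScreeningResult:
    """Greedy priority-order screen: keep a variable iff ``|r| < threshold``
    against every already-kept variable; record the first blocking partner
    otherwise.

    ``priority`` defaults to the matrix's variable order and must cover all
    variables.
    """
    if priority is None:
        priority = list(corr.variables)
    priority = list(priority)
    if set(priority) != set(corr.variables):
        raise ValueError("priority list must cover exactly the correlated variables")

    kept: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for var in priority:
        blocker = None
        for prev in kept:
            absr = abs(corr.get(var, prev))
            if absr >= threshold:
                blocker = (prev, absr)
                break
        if blocker is None:
            kept.append(var)
        else:
            dropped.append((var, blocker[0], blocker[1]))
            logger.info(
                "dropping %s (|r|=%.3f with kept %s)", var, blocker[1], blocker[0]
            )
    return ScreeningResult(kept=kept, dropped=dropped, threshold=threshold)
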