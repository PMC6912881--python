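"""Committee consensus maps, likelihood binarization, and variable importance.

Every selected model's suitability surface is binarized at that model's own
optimal threshold; the binary maps are pooled into a consensus (committee)
map holding, per cell, the fraction of contributing maps that vote presence.
Following the IPCC-AR5 "likely" convention, a cell belongs to the potential
distribution range when *more than* 66% (strictly more than 2/3) of the
members agree.  Future-scenario consensus pools all selected models across
all climate-model (GCM) stacks with equal weight, each member binarized at
its own calibration threshold, then applies the same 2/3 rule.

Variable importance is shuffle-based: permute the focal column, re-predict,
and take ``1 - r`` where ``r`` is the Pearson correlation between original
and permuted-input predictions; the importance is the mean over three
seeded shuffles.  ``1 - r`` is reported unclipped and may exceed 1 when the
permutation anti-correlates the predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .grid_core import AlignmentError, GridSpec, RasterLayer, RasterStack
from .sdm_learners import predict_raster

__all__ = [
    "BinaryMap",
    "ConsensusMap",
    "ImportanceRecord",
    "ScenarioTag",
    "ConsensusError",
    "LIKELY_CUTOFF",
    "binarize_map",
    "consensus_fraction",
    "likelihood_binarize",
    "scenario_consensus",
    "variable_importance",
    "importance_table",
]

logger = logging.getLogger(__name__)

LIKELY_CUTOFF = 2.0 / 3.0


class ConsensusError(ValueError):
    """No consensus possible (e.g. empty selected-model set)."""


@dataclass(frozen=True)
class ScenarioTag:
    """Identifies one projection: period, emission pathway, climate model."""

    period: str = "current"
    rcp: str | None = None
    gcm: str | None = None

    def __post_init__(self) -> None:
        if self.period == "current" and (self.rcp or self.gcm):
            raise ValueError("the current period carries no rcp/gcm")

    def label(self) -> str:
        parts = [self.period]
        if self.rcp:
            parts.append(self.rcp)
        if self.gcm:
            parts.append(self.gcm)
        return "_".join(parts)


@dataclass
class BinaryMap:
    """Presence/absence map with provenance of the models that produced it."""

    grid: GridSpec
    presence: np.ndarray
    mask: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.presence.shape != self.grid.shape or self.mask.shape != self.grid.shape:
            raise ValueError("binary map arrays must match the grid shape")

    def as_layer(self, name: str = "presence") -> RasterLayer:
        return RasterLayer(
            name, self.grid, self.presence.astype(float), self.mask.copy()
        )

    def n_suitable(self) -> int:
        return int((self.presence & ~self.mask).sum())


@dataclass
class ConsensusMap:
    """Per-cell fraction of contributing binary maps voting presence."""

    grid: GridSpec
    fraction: np.ndarray
    n_contributors: np.ndarray

    def as_layer(self, name: str = "consensus") -> RasterLayer:
        mask = self.n_contributors == 0
        return RasterLayer(name, self.grid, np.where(mask, 0.0, self.fraction), mask)


@dataclass
class ImportanceRecord:
    species: str
    variable: str
    values: list[float]
    importance: float


def binarize_map(scores: RasterLayer, tau: float, provenance: str = "") -> BinaryMap:
    """Threshold a suitability surface: presence iff ``score >= tau``."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"threshold {tau} outside [0, 1]")
    presence = (scores.values >= tau) & ~scores.mask
    return BinaryMap(
        scores.grid, presence, scores.mask.copy(),
        provenance=[provenance] if provenance else [],
    )


def consensus_fraction(maps: Sequence[BinaryMap]) -> ConsensusMap:
    """Per-cell mean of presence votes over the maps where the cell is off-mask."""
    maps = list(maps)
    if not maps:
        raise ConsensusError("no consensus possible: empty map list")
    grid = maps[0].grid
    votes = np.zeros(grid.shape)
    contributors = np.zeros(grid.shape, dtype=np.int64)
    for m in maps:
        if m.grid != grid:
            raise AlignmentError("consensus requires all maps on one grid")
        off = ~m.mask
        votes[off] += m.presence[off]
        contributors[off] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        fraction = np.where(contributors > 0, votes / np.maximum(contributors, 1), 0.0)
    return ConsensusMap(grid, fraction, contributors)


def likelihood_binarize(consensus: ConsensusMap, cutoff: float = LIKELY_CUTOFF) -> BinaryMap:
    """Suitable iff strictly more than ``cutoff`` of the members vote presence."""
    mask = consensus.n_contributors == 0
    presence = (consensus.fraction > cutoff) & ~mask
    return BinaryMap(consensus.grid, presence, mask,
                     provenance=[f"likelihood>{cutoff:.4f}"])


def scenario_consensus(
    models: Sequence[tuple[object, float]],
    stacks: Sequence[tuple[RasterStack, str]],
    cutoff: float = LIKELY_CUTOFF,
) -> BinaryMap:
    """Pool |models| x |stacks| binary maps into one likelihood-binarized map.

    ``models`` holds ``(fitted model, its own optimal threshold)``; ``stacks``
    holds ``(predictor stack, label)`` — one stack per GCM for a given
    (period, pathway).  Every member is weighted equally.
    """
    models = list(models)
    stacks = list(stacks)
    if not models:
        raise ConsensusError("no consensus possible: empty selected-model set")
    if not stacks:
        raise ConsensusError("no consensus possible: no scenario stacks")
    members: list[BinaryMap] = []
    for m_i, (model, tau) in enumerate(models):
        for stack, label in stacks:
            scores = predict_raster(model, stack)
            members.append(binarize_map(scores, tau, provenance=f"m{m_i}@{label}"))
    pooled = consensus_fraction(members)
    out = likelihood_binarize(pooled, cutoff)
    out.provenance = [p for m in members for p in m.provenance]
    return out


def variable_importance(
    model,
    design: pd.DataFrame,
    variable: str,
    n_shuffles: int = 3,
    seed: int = 0,
    species: str = "",
) -> ImportanceRecord:
    """Shuffle-based importance: mean over shuffles of ``1 - r``.

    ``r`` is the Pearson correlation between predictions from the original
    design and from a design whose focal column is permuted (shuffle k uses
    the derived seed ``(seed, k)``).  Constant predictions under either input
    make ``r`` undefined; that shuffle is recorded as importance 0 with a
    warning.
    """
    if variable not in design.columns:
        raise KeyError(f"variable {variable!r} not in design table")
    base = np.asarray(model.predict_suitability(design), dtype=float)
    values: list[float] = []
    for k in range(n_shuffles):
        rng = np.random.default_rng([seed, k])
        shuffled = design.copy()
        shuffled[variable] = rng.permutation(shuffled[variable].to_numpy())
        pred = np.asarray(model.predict_suitability(shuffled), dtype=float)
        if np.std(base) == 0 or np.std(pred) == 0:
            logger.warning(
                "constant predictions while shuffling %s; recording importance 0",
                variable,
            )
            values.append(0.0)
            continue
        r = float(np.corrcoef(base, pred)[0, 1])
        values.append(1.0 - r)
    return ImportanceRecord(
        species=species,
        variable=variable,
        values=values,
        importance=float(np.mean(values)),
    )


def importance_table(records: Sequence[ImportanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "variable": r.variable,
                "importance": r.importance,
                **{f"shuffle_{k + 1}": v for k, v in enumerate(r.values)},
            }
            for r in records
        ]
    )
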