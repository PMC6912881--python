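"""End-to-end orchestration: survey + rasters -> evaluated ensemble -> maps.

Stage order: distance predictors -> point extraction -> collinearity screen
-> calibrate every learner on R random 75/25 splits -> held-out AUC/TSS
evaluation -> AUC/TSS admission gate -> current-climate consensus map and
likelihood binarization -> shuffle importance -> scenario consensus across
GCMs -> gain/loss/net range-change accounting.  Species are processed
independently.  Every stage is a pure function of (inputs, config, seed),
so one config + seed reproduces the run report byte-for-byte (modulo its
timestamp field).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .grid_core import RasterStack, extract_at_points, validate_occurrences, write_raster
from .predictor_prep import collinearity_filter, correlation_matrix
from .sdm_learners import make_learner, predict_raster
from .evaluation import (
    EvalRecord,
    SelectionRule,
    evaluate_model,
    records_to_frame,
    select_models,
    split_data,
)
from .ensemble_consensus import (
    LIKELY_CUTOFF,
    binarize_map,
    consensus_fraction,
    importance_table,
    likelihood_binarize,
    scenario_consensus,
    variable_importance,
)
from .range_change import change_summary, classify_change
from .synthetic_data import SyntheticConfig, SyntheticDataset, generate_dataset

__all__ = ["LearnerConfig", "PipelineConfig", "RunReport", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LearnerConfig:
    """One ensemble member family and its hyperparameters."""

    name: str
    family: str
    hyperparameters: Mapping[str, object] = dc_field(default_factory=dict)


DEFAULT_LEARNERS = (
    LearnerConfig("SRE", "envelope", {"q": 0.025}),
    LearnerConfig("GLM", "logistic", {"degree": 2}),
    LearnerConfig("RF", "bagged_trees", {"n_trees": 50, "max_depth": 8, "min_leaf": 5}),
)


@dataclass
class PipelineConfig:
    """All settings of one run; defaults follow the standard protocol
    (10 x 75/25 replicates, |r| < 0.70 screen, AUC > 0.8 & TSS > 0.45 gate,
    2/3 consensus cutoff)."""

    learners: Sequence[LearnerConfig] = DEFAULT_LEARNERS
    replicates: int = 10
    calibration_fraction: float = 0.75
    screening_threshold: float = 0.70
    priority: Sequence[str] | None = None
    selection: SelectionRule = dc_field(default_factory=SelectionRule)
    consensus_cutoff: float = LIKELY_CUTOFF
    importance_shuffles: int = 3
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "learners": [
                {"name": l.name, "family": l.family,
                 "hyperparameters": dict(l.hyperparameters)}
                for l in self.learners
            ],
            "replicates": self.replicates,
            "calibration_fraction": self.calibration_fraction,
            "screening_threshold": self.screening_threshold,
            "priority": list(self.priority) if self.priority else None,
            "selection": {"min_auc": self.selection.min_auc,
                          "min_tss": self.selection.min_tss},
            "consensus_cutoff": self.consensus_cutoff,
            "importance_shuffles": self.importance_shuffles,
            "seed": self.seed,
        }


@dataclass
class SpeciesResult:
    species: str
    n_sites: int
    n_excluded: int
    kept_variables: list[str]
    dropped_variables: list[tuple[str, str, float]]
    records: list[EvalRecord]
    percent_selected: int
    consensus_possible: bool
    current_map: object | None  # BinaryMap
    consensus_map: object | None  # ConsensusMap
    importance: pd.DataFrame | None
    scenario_maps: dict[tuple[str, str], object]
    change_summaries: dict[tuple[str, str], object]
    fitted: list[tuple[object, float, EvalRecord]]  # (model, tau, record)


@dataclass
class RunReport:
    config: dict
    species: dict[str, SpeciesResult]
    timestamp: str

    def to_dict(self) -> dict:
        out: dict = {
            "version": __version__,
            "timestamp": self.timestamp,
            "config": self.config,
            "config_hash": hashlib.sha256(
                json.dumps(self.config, sort_keys=True).encode()
            ).hexdigest()[:16],
            "species": {},
        }
        for name, res in self.species.items():
            entry = {
                "n_sites": res.n_sites,
                "n_excluded": res.n_excluded,
                "kept_variables": res.kept_variables,
                "dropped_variables": [
                    {"variable": v, "partner": p, "abs_r": round(r, 6)}
                    for v, p, r in res.dropped_variables
                ],
                "evaluation": json.loads(
                    records_to_frame(res.records).to_json(orient="records")
                ),
                "percent_selected": res.percent_selected,
                "consensus_possible": res.consensus_possible,
            }
            if res.consensus_possible:
                entry["current_range_cells"] = res.current_map.n_suitable()
                entry["importance"] = json.loads(
                    res.importance.to_json(orient="records")
                )
                entry["scenarios"] = {
                    "/".join(k): s.to_dict()
                    for k, s in res.change_summaries.items()
                }
            else:
                entry["note"] = "no consensus possible: empty selected-model set"
            out["species"][name] = entry
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _fit_one(learner: LearnerConfig, X, y, seed: int):
    params = dict(learner.hyperparameters)
    if learner.family == "bagged_trees":
        params.setdefault("seed", seed)
    return make_learner(learner.family, **params).fit(X, y)


def run_pipeline(
    config: PipelineConfig,
    data: SyntheticDataset | None = None,
    stack: RasterStack | None = None,
    occurrences: pd.DataFrame | None = None,
    scenario_stacks: Mapping[tuple[str, str], list] | None = None,
    outdir: str | Path | None = None,
) -> RunReport:
    """Run the full analysis and return a machine-readable report.

    Either pass a :class:`SyntheticDataset` (``data=``) or the three raw
    ingredients (predictor ``stack``, ``occurrences`` table and optional
    ``scenario_stacks`` keyed by (period, rcp) holding [(stack, gcm), ...]).
    With ``outdir`` set, rasters and tables are persisted there.
    """
    if data is not None:
        stack = data.stack
        occurrences = data.occurrences
        scenario_stacks = data.scenario_stacks
    if stack is None or occurrences is None:
        raise ValueError("pass either data= or both stack= and occurrences=")
    scenario_stacks = scenario_stacks or {}
    validate_occurrences(occurrences)
    outpath = Path(outdir) if outdir is not None else None
    if outpath is not None:
        outpath.mkdir(parents=True, exist_ok=True)

    cell_area_km2 = stack.grid.cell_size_x * stack.grid.cell_size_y / 1e6
    results: dict[str, SpeciesResult] = {}

    for species in sorted(occurrences["species"].unique()):
        logger.info("=== species %s ===", species)
        table = occurrences[occurrences["species"] == species].reset_index(drop=True)
        design, n_excluded = extract_at_points(stack, table)
        y = design["presence"].to_numpy(float)
        n = len(design)

        corr = correlation_matrix(design, variables=stack.names)
        screening = collinearity_filter(
            corr, threshold=config.screening_threshold,
            priority=list(config.priority) if config.priority else None,
        )
        kept = screening.kept
        logger.info("kept %d/%d variables: %s", len(kept), len(stack.names), kept)
        X = design[kept]

        records: list[EvalRecord] = []
        fitted: list[tuple[object, float, EvalRecord]] = []
        for r in range(1, config.replicates + 1):
            plan = split_data(
                n, fraction=config.calibration_fraction, replicate=r,
                seed=config.seed,
            )
            for li, learner in enumerate(config.learners):
                model = _fit_one(
                    learner, X.iloc[plan.calibration], y[plan.calibration],
                    seed=config.seed + 1000 * r + li,
                )
                rec = evaluate_model(
                    model, X.iloc[plan.test], y[plan.test],
                    species=species, algorithm=learner.name, replicate=r,
                )
                records.append(rec)
                fitted.append((model, rec.threshold, rec))

        selected_records, percent = select_models(records, config.selection)
        selected = [
            (m, tau, rec) for (m, tau, rec) in fitted if rec.selected
        ]
        logger.info("%d/%d models selected (%d%%)", len(selected), len(records), percent)

        if not selected:
            results[species] = SpeciesResult(
                species=species, n_sites=n, n_excluded=n_excluded,
                kept_variables=kept, dropped_variables=screening.dropped,
                records=records, percent_selected=percent,
                consensus_possible=False, current_map=None, consensus_map=None,
                importance=None, scenario_maps={}, change_summaries={},
                fitted=fitted,
            )
            continue

        # current-climate consensus
        member_maps = [
            binarize_map(predict_raster(m, stack), tau,
                         provenance=f"{rec.algorithm}/r{rec.replicate}")
            for m, tau, rec in selected
        ]
        consensus = consensus_fraction(member_maps)
        current_map = likelihood_binarize(consensus, config.consensus_cutoff)

        # shuffle importance, averaged over the selected models; each model
        # is probed on its own calibration rows
        imp_rows = []
        for mi, (m, _tau, rec) in enumerate(selected):
            plan = split_data(
                n, fraction=config.calibration_fraction, replicate=rec.replicate,
                seed=config.seed,
            )
            rows = design.iloc[plan.calibration][kept]
            for var in kept:
                imp_rows.append(
                    variable_importance(
                        m, rows, var, n_shuffles=config.importance_shuffles,
                        seed=config.seed + 31 * mi, species=species,
                    )
                )
        imp = importance_table(imp_rows)
        imp_mean = (
            imp.groupby(["species", "variable"], sort=False)["importance"]
            .mean().reset_index()
        )

        scenario_maps = {}
        summaries = {}
        for key, stacks in scenario_stacks.items():
            fut_map = scenario_consensus(
                [(m, tau) for m, tau, _ in selected], stacks,
                cutoff=config.consensus_cutoff,
            )
            change = classify_change(current_map, fut_map)
            scenario_maps[key] = fut_map
            summaries[key] = change_summary(change, cell_area=cell_area_km2)
            if outpath is not None:
                write_raster(
                    change.as_layer(f"{species}_{'_'.join(key)}_change"),
                    outpath / f"{species}_{'_'.join(key)}_change.asc",
                )

        if outpath is not None:
            write_raster(consensus.as_layer(f"{species}_consensus"),
                         outpath / f"{species}_consensus.asc")
            write_raster(current_map.as_layer(f"{species}_range"),
                         outpath / f"{species}_range.asc")
            records_to_frame(records).to_csv(
                outpath / f"{species}_evaluation.csv", index=False
            )
            imp.to_csv(outpath / f"{species}_importance.csv", index=False)
            screening.write_report(outpath / f"{species}_screening.csv")

        results[species] = SpeciesResult(
            species=species, n_sites=n, n_excluded=n_excluded,
            kept_variables=kept, dropped_variables=screening.dropped,
            records=records, percent_selected=percent,
            consensus_possible=True, current_map=current_map,
            consensus_map=consensus, importance=imp_mean,
            scenario_maps=scenario_maps, change_summaries=summaries,
            fitted=fitted,
        )

    report = RunReport(
        config=config.to_dict(),
        species=results,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
    )
    if outpath is not None:
        report.to_json(outpath / "report.json")
    return report
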