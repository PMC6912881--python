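"""Virtual landscapes and virtual species with known truth.

Real occurrence data never come with the true suitability surface, so the
pipeline is validated on virtual species: smooth, mutually correlated
climate surfaces on a projected grid, waterbody masks feeding the eikonal
distance predictors, a known logistic suitability function of a subset of
predictors, Bernoulli presence/absence surveys, and future climate stacks
built from additive deltas with between-GCM jitter.  Everything is
reproducible from the top-level seed, and the true suitability and range
maps are always retained so recovery can be scored.

Climate surfaces are built as ``directional gradient + Gaussian-smoothed
white noise``, one basis field per variable; when a target inter-variable
correlation matrix is given, the basis fields are orthonormalised across
cells and mixed through the Cholesky factor of the target matrix, so the
realised correlations land close to the targets.  Each surface is then
affinely rescaled to its stated physical range.

Defaults emulate a temperate desert basin: a 120 x 120 grid of 1-km cells,
six bioclimatic surfaces (MAT, MDR, ISO, MTCM, PWM, PCQ) spanning
basin-realistic ranges, fresh and salty waterbodies, and a survey of ~2,500
sites.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grid_core import GridSpec, RasterLayer, RasterStack
from .ensemble_consensus import BinaryMap, ScenarioTag
from .water_distance import SourceMask, fmm_distance

__all__ = [
    "VariableRecipe",
    "LandscapeSpec",
    "VirtualSpeciesSpec",
    "ScenarioDelta",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_climate_stack",
    "generate_water_mask",
    "true_suitability",
    "true_range",
    "sample_survey",
    "apply_scenario",
    "generate_dataset",
    "default_grid",
    "default_landscape",
    "default_species",
    "default_scenarios",
]

logger = logging.getLogger(__name__)

CLIMATE_VARIABLES = ["MAT", "MDR", "ISO", "MTCM", "PWM", "PCQ"]
DISTANCE_VARIABLES = ["DIST_F", "DIST_S"]


def _seed_of(label: str) -> int:
    """Stable 31-bit integer from a text label, for derived seeds."""
    return zlib.crc32(label.encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class VariableRecipe:
    """Recipe for one climate surface.

    ``gradient`` weights the normalised east/north coordinates; the noise
    term is white noise smoothed with a Gaussian kernel of ``smoothing``
    cells and weighted by ``noise``; the finished surface is rescaled to
    ``value_range``.
    """

    gradient: tuple[float, float]
    noise: float
    smoothing: float
    value_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.smoothing < 1:
            raise ValueError("smoothing length must be >= 1 cell")
        if self.value_range[1] <= self.value_range[0]:
            raise ValueError("value_range must be increasing")


def default_grid(n: int = 120, cell: float = 1000.0) -> GridSpec:
    """Projected n x n grid of 1-km cells (metric units)."""
    return GridSpec(
        n_rows=n, n_cols=n, x_origin=500_000.0, y_origin=5_000_000.0,
        cell_size_x=cell, cell_size_y=cell,
    )


_DEFAULT_RECIPES: dict[str, VariableRecipe] = {
    "MAT": VariableRecipe((0.8, -0.5), 0.35, 8.0, (1.3, 9.8)),
    "MDR": VariableRecipe((-0.3, 0.6), 0.45, 6.0, (10.0, 16.0)),
    "ISO": VariableRecipe((0.5, 0.5), 0.45, 6.0, (25.0, 40.0)),
    "MTCM": VariableRecipe((0.7, -0.6), 0.35, 8.0, (-25.0, -12.0)),
    "PWM": VariableRecipe((-0.6, 0.3), 0.55, 5.0, (10.0, 35.0)),
    "PCQ": VariableRecipe((-0.5, -0.4), 0.55, 5.0, (15.0, 60.0)),
}

# Moderate bioclimatic cross-correlations: the two temperature extremes track
# each other strongly, diurnal range tracks isothermality, the two
# precipitation summaries track each other, temperature and precipitation are
# weakly opposed.
_DEFAULT_TARGET_R = np.array(
    [
        # MAT   MDR   ISO  MTCM   PWM   PCQ
        [1.00, 0.20, 0.30, 0.80, -0.30, -0.20],
        [0.20, 1.00, 0.50, 0.10, -0.20, -0.10],
        [0.30, 0.50, 1.00, 0.20, -0.10, -0.10],
        [0.80, 0.10, 0.20, 1.00, -0.20, -0.10],
        [-0.30, -0.20, -0.10, -0.20, 1.00, 0.60],
        [-0.20, -0.10, -0.10, -0.10, 0.60, 1.00],
    ]
)


@dataclass
class LandscapeSpec:
    """Grid, per-variable recipes, optional target correlations, and seed."""

    grid: GridSpec = dc_field(default_factory=default_grid)
    recipes: Mapping[str, VariableRecipe] = dc_field(
        default_factory=lambda: dict(_DEFAULT_RECIPES)
    )
    target_correlation: np.ndarray | None = dc_field(
        default_factory=lambda: _DEFAULT_TARGET_R.copy()
    )
    seed: int = 0


def _basis_field(grid: GridSpec, recipe: VariableRecipe, rng: np.random.Generator) -> np.ndarray:
    ii, jj = np.meshgrid(
        np.linspace(0, 1, grid.n_rows), np.linspace(0, 1, grid.n_cols), indexing="ij"
    )
    east, north = jj, 1.0 - ii  # north grows toward row 0
    plane = recipe.gradient[0] * east + recipe.gradient[1] * north
    if recipe.noise > 0:
        noise = gaussian_filter(
            rng.standard_normal(grid.shape), sigma=recipe.smoothing, mode="reflect"
        )
        std = noise.std()
        if std > 0:
            noise /= std
        raw = plane + recipe.noise * noise
    else:
        raw = plane
    return raw


def _standardize(flat: np.ndarray) -> np.ndarray:
    std = flat.std()
    return (flat - flat.mean()) / (std if std > 0 else 1.0)


def generate_climate_stack(spec: LandscapeSpec) -> RasterStack:
    """Generate the climate surfaces of a landscape spec.

    With a target correlation matrix, basis fields are orthonormalised (QR
    across cells) and mixed with the Cholesky factor of the target; without
    one, every variable is exactly its own recipe field.  Realised pairwise
    correlations are checked against the targets (logged when off by more
    than 0.15).
    """
    names = list(spec.recipes)
    grid = spec.grid
    rng = np.random.default_rng(spec.seed)
    raw = np.column_stack(
        [_basis_field(grid, spec.recipes[n], rng).ravel() for n in names]
    )

    if spec.target_correlation is not None:
        target = np.asarray(spec.target_correlation, dtype=float)
        k = len(names)
        if target.shape != (k, k):
            raise ValueError("target correlation shape must match variable count")
        try:
            L = np.linalg.cholesky(target)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "target correlation matrix is not positive definite"
            ) from exc
        centered = raw - raw.mean(axis=0)
        q, _ = np.linalg.qr(centered)
        basis = q * np.sqrt(len(q))  # orthonormal columns with unit variance
        # keep each basis column pointing the way its recipe field does
        sign = np.sign(np.einsum("ij,ij->j", centered, basis))
        sign[sign == 0] = 1.0
        mixed = (basis * sign) @ L.T
    else:
        mixed = np.column_stack([_standardize(raw[:, i]) for i in range(len(names))])

    layers = []
    for i, name in enumerate(names):
        fld = mixed[:, i].reshape(grid.shape)
        lo, hi = spec.recipes[name].value_range
        fmin, fmax = fld.min(), fld.max()
        if fmax > fmin:
            fld = lo + (fld - fmin) * (hi - lo) / (fmax - fmin)
        else:
            fld = np.full(grid.shape, (lo + hi) / 2.0)
        layers.append(RasterLayer(name, grid, fld))
    stack = RasterStack(layers)

    if spec.target_correlation is not None:
        realized = np.corrcoef(
            np.column_stack([stack[n].values.ravel() for n in names]), rowvar=False
        )
        err = np.abs(realized - np.asarray(spec.target_correlation))
        worst = float(err[np.triu_indices(len(names), 1)].max()) if len(names) > 1 else 0.0
        log = logger.warning if worst > 0.15 else logger.info
        log("realized correlations deviate from targets by at most %.3f", worst)
    return stack


def generate_water_mask(
    grid: GridSpec, n_rivers: int = 1, n_lakes: int = 2, seed: int = 0
) -> SourceMask:
    """Random waterbodies: rivers as 4-connected west-to-east random walks
    (one cell wide), lakes as random ellipses."""
    if n_rivers < 0 or n_lakes < 0:
        raise ValueError("feature counts must be >= 0")
    rng = np.random.default_rng(seed)
    is_source = np.zeros(grid.shape, dtype=bool)
    n_rows, n_cols = grid.shape

    for _ in range(n_rivers):
        i = int(rng.integers(n_rows // 4, 3 * n_rows // 4))
        j = 0
        is_source[i, j] = True
        while j < n_cols - 1:
            if rng.random() < 0.6:
                j += 1
            else:
                i = int(np.clip(i + (1 if rng.random() < 0.5 else -1), 0, n_rows - 1))
            is_source[i, j] = True

    for _ in range(n_lakes):
        ci = rng.integers(5, max(6, n_rows - 5))
        cj = rng.integers(5, max(6, n_cols - 5))
        ri = rng.integers(2, 7)
        rj = rng.integers(2, 7)
        ii, jj = np.ogrid[:n_rows, :n_cols]
        is_source |= ((ii - ci) / ri) ** 2 + ((jj - cj) / rj) ** 2 <= 1.0

    if n_rivers + n_lakes == 0:
        logger.warning("water mask generated with zero features (empty mask)")
    return SourceMask(grid, is_source)


# ---------------------------------------------------------------------------
# Virtual species
# ---------------------------------------------------------------------------


@dataclass
class VirtualSpeciesSpec:
    """Known logistic truth: pi = expit(b0 + sum b_j z_j + sum g_j z_j^2).

    ``z`` are predictors standardised by the *current* landscape's off-mask
    mean and standard deviation (so future stacks shift suitability rather
    than being re-standardised away).  Occupancy truth maps use pi > 0.5;
    surveys observe presence with probability ``pi * detection``.
    """

    name: str = "virtual"
    beta0: float = 0.0
    betas: Mapping[str, float] = dc_field(default_factory=dict)
    gammas: Mapping[str, float] = dc_field(default_factory=dict)
    detection: float = 1.0

    def __post_init__(self) -> None:
        if not any(v != 0 for v in self.betas.values()):
            raise ValueError("at least one nonzero linear coefficient required")
        if not 0.0 <= self.detection <= 1.0:
            raise ValueError("detection must be in [0, 1]")

    @property
    def variables(self) -> list[str]:
        return sorted(set(self.betas) | set(self.gammas))


def true_suitability(
    species: VirtualSpeciesSpec,
    stack: RasterStack,
    reference: RasterStack | None = None,
) -> RasterLayer:
    """True suitability surface of a virtual species on a stack.

    Standardisation constants come from ``reference`` (default: the stack
    itself); pass the current-climate stack when projecting onto futures.
    """
    ref = reference if reference is not None else stack
    mask = stack.combined_mask()
    eta = np.full(stack.grid.shape, species.beta0)
    for var in species.variables:
        ref_vals = ref[var].values[~ref[var].mask]
        mu, sd = ref_vals.mean(), ref_vals.std()
        z = (stack[var].values - mu) / (sd if sd > 0 else 1.0)
        eta = eta + species.betas.get(var, 0.0) * z + species.gammas.get(var, 0.0) * z ** 2
    pi = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    return RasterLayer(f"pi_{species.name}", stack.grid, np.where(mask, 0.0, pi), mask)


def true_range(pi: RasterLayer, cutoff: float = 0.5) -> BinaryMap:
    """Occupancy truth map: suitable iff pi > cutoff."""
    return BinaryMap(pi.grid, (pi.values > cutoff) & ~pi.mask, pi.mask.copy(),
                     provenance=["truth"])


def sample_survey(
    stack: RasterStack,
    species: VirtualSpeciesSpec,
    n_sites: int = 2500,
    design: str = "uniform",
    seed: int = 0,
    reference: RasterStack | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Survey ``n_sites`` distinct cells and record Bernoulli presence.

    ``design='uniform'`` draws cells uniformly without replacement;
    ``design='transect'`` takes cells along evenly spaced west-east rows
    (road-survey style) and thins them at random.  Returns the occurrence
    table and a truth table ``(site_id, pi)``.
    """
    rng = np.random.default_rng(seed)
    mask = stack.combined_mask()
    ok_rows, ok_cols = np.nonzero(~mask)
    n_ok = len(ok_rows)
    if n_sites > n_ok:
        raise ValueError(f"n_sites={n_sites} exceeds {n_ok} available cells")

    if design == "uniform":
        pick = rng.choice(n_ok, size=n_sites, replace=False)
    elif design == "transect":
        n_transects = max(1, int(np.ceil(n_sites / stack.grid.n_cols)))
        rows = np.unique(
            np.linspace(0, stack.grid.n_rows - 1, n_transects).round().astype(int)
        )
        on_transect = np.nonzero(np.isin(ok_rows, rows))[0]
        if len(on_transect) < n_sites:
            raise ValueError("not enough transect cells for the requested n_sites")
        pick = rng.choice(on_transect, size=n_sites, replace=False)
    else:
        raise ValueError(f"unknown survey design {design!r}")
    pick = np.sort(pick)
    rows_p, cols_p = ok_rows[pick], ok_cols[pick]

    pi_layer = true_suitability(species, stack, reference=reference)
    pi = pi_layer.values[rows_p, cols_p]
    presence = rng.binomial(1, np.clip(pi * species.detection, 0.0, 1.0))

    xc = stack.grid.x_centers()[cols_p]
    yc = stack.grid.y_centers()[rows_p]
    site_ids = [f"S{k:05d}" for k in range(n_sites)]
    table = pd.DataFrame(
        {
            "site_id": site_ids,
            "x": xc,
            "y": yc,
            "species": species.name,
            "presence": presence.astype(int),
        }
    )
    truth = pd.DataFrame({"site_id": site_ids, "pi": pi})
    return table, truth


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


@dataclass
class ScenarioDelta:
    """Additive climate deltas for one (period, pathway).

    ``constants`` shifts each named climate variable uniformly;
    ``perturbation`` optionally adds a smooth spatial component
    ``(amplitude, smoothing length)``; ``gcm_jitter`` is the between-GCM
    spread: each GCM adds its own smooth field of that per-cell standard
    deviation.  Distance and topographic variables are never touched.
    """

    tag: ScenarioTag
    constants: Mapping[str, float]
    perturbation: Mapping[str, tuple[float, float]] = dc_field(default_factory=dict)
    gcm_jitter: float = 0.0
    jitter_smoothing: float = 6.0


def _smooth_unit_field(grid: GridSpec, smoothing: float, rng: np.random.Generator) -> np.ndarray:
    fld = gaussian_filter(rng.standard_normal(grid.shape), sigma=smoothing, mode="reflect")
    std = fld.std()
    return fld / (std if std > 0 else 1.0)


def apply_scenario(
    stack: RasterStack, delta: ScenarioDelta, seed: int = 0, gcm: str | None = None
) -> RasterStack:
    """Future predictor stack for one GCM under one (period, pathway) delta.

    Climate layers are shifted by constant + smooth perturbation (shared by
    all GCMs of the scenario) + GCM-specific jitter seeded from
    ``(seed, gcm label)``; all other layers are copied unchanged.
    """
    gcm = gcm if gcm is not None else delta.tag.gcm
    unknown = [
        v for v in set(delta.constants) | set(delta.perturbation) if v not in stack
    ]
    if unknown:
        raise ValueError(f"scenario delta names unknown variable(s) {sorted(unknown)}")
    non_climate = [
        v for v in set(delta.constants) | set(delta.perturbation)
        if v in DISTANCE_VARIABLES
    ]
    if non_climate:
        raise ValueError(
            f"scenario delta must cover climate variables only, got {sorted(non_climate)}"
        )

    new_layers = []
    for lyr in stack:
        name = lyr.name
        if name not in delta.constants and name not in delta.perturbation:
            continue
        shift = np.full(stack.grid.shape, float(delta.constants.get(name, 0.0)))
        if name in delta.perturbation:
            amp, smooth = delta.perturbation[name]
            rng = np.random.default_rng([seed, _seed_of(delta.tag.label()), _seed_of(name)])
            shift = shift + amp * _smooth_unit_field(stack.grid, smooth, rng)
        if delta.gcm_jitter > 0 and gcm is not None:
            rng = np.random.default_rng([seed, _seed_of(gcm), _seed_of(name)])
            shift = shift + delta.gcm_jitter * _smooth_unit_field(
                stack.grid, delta.jitter_smoothing, rng
            )
        new_layers.append(
            RasterLayer(name, lyr.grid, lyr.values + shift, lyr.mask.copy())
        )
    return stack.replace(new_layers)


# ---------------------------------------------------------------------------
# Whole-dataset convenience
# ---------------------------------------------------------------------------


def default_landscape(seed: int = 0, n: int = 120) -> LandscapeSpec:
    return LandscapeSpec(grid=default_grid(n=n), seed=seed)


def default_species() -> VirtualSpeciesSpec:
    """Two-variable logistic truth: warm, wet-summer habitat."""
    return VirtualSpeciesSpec(
        name="virtual", beta0=-0.5, betas={"MAT": 2.0, "PWM": 1.5}
    )


def default_scenarios() -> list[ScenarioDelta]:
    """One moderate warming scenario (2050s) with three jittered GCMs."""
    return [
        ScenarioDelta(
            tag=ScenarioTag(period="2050s", rcp="RCP4.5"),
            constants={"MAT": 2.0, "MTCM": 2.0, "PWM": 2.0, "PCQ": 2.0},
            gcm_jitter=0.3,
        )
    ]


DEFAULT_GCMS = ["GCM-A", "GCM-B", "GCM-C"]


@dataclass
class SyntheticConfig:
    landscape: LandscapeSpec
    species: list[VirtualSpeciesSpec]
    n_sites: int = 2500
    survey_design: str = "uniform"
    scenarios: list[ScenarioDelta] = dc_field(default_factory=default_scenarios)
    gcms: list[str] = dc_field(default_factory=lambda: list(DEFAULT_GCMS))
    n_rivers: int = 1
    n_lakes: int = 2
    seed: int = 0


@dataclass
class SyntheticDataset:
    """Everything one pipeline run needs, plus the truth for scoring."""

    config: SyntheticConfig
    stack: RasterStack  # climate + DIST_F + DIST_S, current period
    fresh_mask: SourceMask
    salty_mask: SourceMask
    occurrences: pd.DataFrame
    truth_pi: dict[str, RasterLayer]
    truth_range: dict[str, BinaryMap]
    scenario_stacks: dict[tuple[str, str], list[tuple[RasterStack, str]]]
    truth_future_range: dict[tuple[str, str, str], BinaryMap]


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate landscape, water distances, survey, truth and scenario stacks.

    Fully deterministic from ``config.seed`` (sub-stages use derived seeds).
    Distance layers are in km, matching their conventional units on 1-km
    metric grids.
    """
    land = config.landscape
    land.seed = config.seed
    climate = generate_climate_stack(land)
    grid = land.grid

    fresh = generate_water_mask(grid, config.n_rivers, 1, seed=config.seed + 101)
    salty = generate_water_mask(grid, 0, config.n_lakes, seed=config.seed + 202)
    dist_f = fmm_distance(fresh).as_layer("DIST_F", unit_scale=1e-3)
    dist_s = fmm_distance(salty).as_layer("DIST_S", unit_scale=1e-3)
    stack = RasterStack(list(climate) + [dist_f, dist_s])

    tables = []
    truth_pi: dict[str, RasterLayer] = {}
    truth_rng: dict[str, BinaryMap] = {}
    for k, sp in enumerate(config.species):
        table, _ = sample_survey(
            stack, sp, n_sites=config.n_sites, design=config.survey_design,
            seed=config.seed + 303 + k,
        )
        tables.append(table)
        pi = true_suitability(sp, stack)
        truth_pi[sp.name] = pi
        truth_rng[sp.name] = true_range(pi)

    scenario_stacks: dict[tuple[str, str], list[tuple[RasterStack, str]]] = {}
    truth_future: dict[tuple[str, str, str], BinaryMap] = {}
    for delta in config.scenarios:
        key = (delta.tag.period, delta.tag.rcp or "")
        per_gcm = []
        for gcm in config.gcms:
            fut = apply_scenario(stack, delta, seed=config.seed + 404, gcm=gcm)
            per_gcm.append((fut, gcm))
        scenario_stacks[key] = per_gcm
        # truth under the ensemble-mean delta (no jitter): the scenario's
        # signal, against which recovered change is scored
        clean = ScenarioDelta(
            tag=delta.tag, constants=delta.constants,
            perturbation=delta.perturbation, gcm_jitter=0.0,
        )
        fut_clean = apply_scenario(stack, clean, seed=config.seed + 404, gcm=None)
        for sp in config.species:
            pi_fut = true_suitability(sp, fut_clean, reference=stack)
            truth_future[(sp.name,) + key] = true_range(pi_fut)

    return SyntheticDataset(
        config=config,
        stack=stack,
        fresh_mask=fresh,
        salty_mask=salty,
        occurrences=pd.concat(tables, ignore_index=True),
        truth_pi=truth_pi,
        truth_range=truth_rng,
        scenario_stacks=scenario_stacks,
        truth_future_range=truth_future,
    )
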