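"""Virtual landscapes, species, surveys and scenarios: determinism and truth."""

import numpy as np
import pytest
from scipy import ndimage

from aridrange.grid_core import RasterStack
from aridrange.synthetic_data import (
    LandscapeSpec,
    ScenarioDelta,
    SyntheticConfig,
    VariableRecipe,
    VirtualSpeciesSpec,
    apply_scenario,
    default_grid,
    default_landscape,
    default_species,
    generate_climate_stack,
    generate_dataset,
    generate_water_mask,
    sample_survey,
    true_range,
    true_suitability,
)
from aridrange.ensemble_consensus import ScenarioTag


def two_var_spec(target_r=None, noise=0.4, seed=0, n=60):
    recipes = {
        "V1": VariableRecipe((1.0, 0.0), noise, 5.0, (0.0, 1.0)),
        "V2": VariableRecipe((0.0, 1.0), noise, 5.0, (0.0, 1.0)),
    }
    return LandscapeSpec(
        grid=default_grid(n=n), recipes=recipes,
        target_correlation=target_r, seed=seed,
    )


class TestClimateStack:
    def test_zero_noise_gives_exact_planar_field(self):
        spec = two_var_spec(target_r=None, noise=0.0)
        stack = generate_climate_stack(spec)
        v = stack["V1"].values
        # planar: second differences vanish in both directions
        assert np.allclose(np.diff(v, 2, axis=1), 0, atol=1e-10)
        assert np.allclose(np.diff(v, 2, axis=0), 0, atol=1e-10)

    def test_same_seed_reproduces_bitwise(self):
        a = generate_climate_stack(two_var_spec(seed=5))
        b = generate_climate_stack(two_var_spec(seed=5))
        for name in a.names:
            assert np.array_equal(a[name].values, b[name].values)

    def test_target_correlation_realized(self):
        target = np.array([[1.0, 0.9], [0.9, 1.0]])
        stack = generate_climate_stack(two_var_spec(target_r=target, n=120))
        r = np.corrcoef(stack["V1"].values.ravel(), stack["V2"].values.ravel())[0, 1]
        assert abs(r - 0.9) <= 0.15

    def test_values_respect_stated_ranges(self):
        stack = generate_climate_stack(default_landscape(seed=3))
        mat = stack["MAT"].values
        assert mat.min() == pytest.approx(1.3) and mat.max() == pytest.approx(9.8)

    def test_infeasible_correlation_matrix_rejected(self):
        bad = np.array([[1.0, 0.9], [0.9, -1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            generate_climate_stack(two_var_spec(target_r=bad))


class TestWaterMask:
    def test_river_is_connected_and_spans_west_to_east(self):
        grid = default_grid(n=50)
        mask = generate_water_mask(grid, n_rivers=1, n_lakes=0, seed=2)
        lab, nlab = ndimage.label(mask.is_source, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        spans = [
            l for l in range(1, nlab + 1)
            if (lab[:, 0] == l).any() and (lab[:, -1] == l).any()
        ]
        assert len(spans) >= 1

    def test_zero_features_is_empty_and_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            mask = generate_water_mask(default_grid(n=20), 0, 0, seed=0)
        assert mask.n_sources == 0 and "zero features" in caplog.text

    def test_same_seed_identical(self):
        g = default_grid(n=40)
        a = generate_water_mask(g, 2, 2, seed=9)
        b = generate_water_mask(g, 2, 2, seed=9)
        assert np.array_equal(a.is_source, b.is_source)


class TestVirtualSpecies:
    def test_all_zero_betas_rejected(self):
        with pytest.raises(ValueError):
            VirtualSpeciesSpec(betas={"MAT": 0.0})

    def test_detection_zero_means_all_absences(self):
        stack = generate_climate_stack(default_landscape(seed=1, n=40))
        sp = VirtualSpeciesSpec(name="v", beta0=2.0, betas={"MAT": 1.0}, detection=0.0)
        table, _ = sample_survey(stack, sp, n_sites=200, seed=0)
        assert table["presence"].sum() == 0

    def test_near_one_suitability_means_all_presences(self):
        stack = generate_climate_stack(default_landscape(seed=1, n=40))
        sp = VirtualSpeciesSpec(name="v", beta0=25.0, betas={"MAT": 1e-6})
        table, _ = sample_survey(stack, sp, n_sites=200, seed=0)
        assert table["presence"].min() == 1

    def test_prevalence_tracks_mean_suitability(self):
        stack = generate_climate_stack(default_landscape(seed=4))
        sp = default_species()
        table, truth = sample_survey(stack, sp, n_sites=2500, seed=1)
        mean_pi = truth["pi"].mean()
        se = np.sqrt((truth["pi"] * (1 - truth["pi"])).sum()) / len(truth)
        assert abs(table["presence"].mean() - mean_pi) <= 3 * se

    def test_truth_range_is_pi_above_half(self):
        stack = generate_climate_stack(default_landscape(seed=2, n=40))
        pi = true_suitability(default_species(), stack)
        rng_map = true_range(pi)
        assert np.array_equal(rng_map.presence, pi.values > 0.5)

    def test_survey_sites_are_distinct_cells(self):
        stack = generate_climate_stack(default_landscape(seed=2, n=40))
        table, _ = sample_survey(stack, default_species(), n_sites=500, seed=3)
        assert len(table[["x", "y"]].drop_duplicates()) == 500

    def test_transect_design_samples_rows(self):
        stack = generate_climate_stack(default_landscape(seed=2, n=40))
        table, _ = sample_survey(stack, default_species(), n_sites=120,
                                 design="transect", seed=3)
        assert table["y"].nunique() <= 4  # few west-east road lines

    def test_oversized_survey_rejected(self):
        stack = generate_climate_stack(default_landscape(seed=2, n=20))
        with pytest.raises(ValueError, match="n_sites"):
            sample_survey(stack, default_species(), n_sites=10_000)


class TestScenario:
    @staticmethod
    def stack40(seed=1):
        return generate_climate_stack(default_landscape(seed=seed, n=40))

    def test_zero_delta_zero_jitter_is_identity(self):
        stack = self.stack40()
        delta = ScenarioDelta(ScenarioTag("2050s", "RCP2.6"), constants={"MAT": 0.0})
        fut = apply_scenario(stack, delta, seed=0, gcm="G")
        assert np.array_equal(fut["MAT"].values, stack["MAT"].values)

    def test_constant_warming_shifts_exactly(self):
        stack = self.stack40()
        delta = ScenarioDelta(ScenarioTag("2050s", "RCP8.5"), constants={"MAT": 2.0})
        fut = apply_scenario(stack, delta, seed=0, gcm="G")
        assert np.allclose(fut["MAT"].values - stack["MAT"].values, 2.0)
        assert np.array_equal(fut["PWM"].values, stack["PWM"].values)

    def test_between_gcm_spread_matches_jitter_amplitude(self):
        stack = self.stack40()
        a = 0.5
        delta = ScenarioDelta(ScenarioTag("2050s", "RCP4.5"),
                              constants={"MAT": 2.0}, gcm_jitter=a)
        futs = [apply_scenario(stack, delta, seed=0, gcm=f"G{i}") for i in range(7)]
        mats = np.stack([f["MAT"].values for f in futs])
        per_cell_sd = mats.std(axis=0, ddof=1)
        assert abs(per_cell_sd.mean() - a) / a <= 0.30

    def test_unknown_variable_in_delta_rejected(self):
        stack = self.stack40()
        delta = ScenarioDelta(ScenarioTag("2050s", "RCP4.5"), constants={"XX": 1.0})
        with pytest.raises(ValueError, match="unknown"):
            apply_scenario(stack, delta, seed=0, gcm="G")

    def test_distance_layers_never_shifted(self):
        cfg = SyntheticConfig(landscape=default_landscape(seed=1, n=40),
                              species=[default_species()], n_sites=300, seed=1)
        ds = generate_dataset(cfg)
        delta = ScenarioDelta(ScenarioTag("2050s", "RCP4.5"),
                              constants={"DIST_F": 1.0})
        with pytest.raises(ValueError, match="climate"):
            apply_scenario(ds.stack, delta, seed=0, gcm="G")


def test_full_dataset_determinism():
    """Two runs from one seed produce byte-identical rasters and tables."""
    def build():
        cfg = SyntheticConfig(landscape=default_landscape(seed=7, n=40),
                              species=[default_species()], n_sites=300, seed=7)
        return generate_dataset(cfg)

    a, b = build(), build()
    for name in a.stack.names:
        assert np.array_equal(a.stack[name].values, b.stack[name].values)
    assert a.occurrences.equals(b.occurrences)
    for key in a.scenario_stacks:
        for (sa, ga), (sb, gb) in zip(a.scenario_stacks[key], b.scenario_stacks[key]):
            assert ga == gb
            assert np.array_equal(sa["MAT"].values, sb["MAT"].values)
    for key in a.truth_range:
        assert np.array_equal(a.truth_range[key].presence, b.truth_range[key].presence)
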