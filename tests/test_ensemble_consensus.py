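"""Binarization, committee consensus, the 2/3 likelihood rule, importance."""

import numpy as np
import pandas as pd
import pytest

from aridrange.grid_core import AlignmentError, RasterLayer, RasterStack
from aridrange.ensemble_consensus import (
    BinaryMap,
    ConsensusError,
    LIKELY_CUTOFF,
    ScenarioTag,
    binarize_map,
    consensus_fraction,
    likelihood_binarize,
    scenario_consensus,
    variable_importance,
)
from aridrange.sdm_learners import LogisticModel

from conftest import unit_grid


def bmap(grid, presence, mask=None):
    return BinaryMap(grid, presence, mask if mask is not None else np.zeros(grid.shape, bool))


class TestBinarize:
    def test_all_below_threshold_all_absent(self, grid3):
        layer = RasterLayer("s", grid3, np.full((3, 3), 0.2))
        assert binarize_map(layer, 0.5).presence.sum() == 0

    def test_score_exactly_at_threshold_is_presence(self, grid3):
        layer = RasterLayer("s", grid3, np.full((3, 3), 0.5))
        assert binarize_map(layer, 0.5).presence.all()

    def test_complement_identity_off_ties(self, grid3, rng):
        s = rng.random((3, 3))
        layer = RasterLayer("s", grid3, s)
        inv = RasterLayer("i", grid3, 1 - s)
        tau = 0.37
        a = binarize_map(layer, tau).presence  # s >= tau
        b = (1 - s) <= 1 - tau  # equivalent rule on the complement
        ties = s == tau
        assert np.array_equal(a[~ties], b[~ties])
        assert np.array_equal(a, ~binarize_map(inv, 1 - tau + 1e-12).presence)

    def test_threshold_outside_unit_interval_rejected(self, grid3):
        layer = RasterLayer("s", grid3, np.zeros((3, 3)))
        with pytest.raises(ValueError):
            binarize_map(layer, 1.5)

    def test_nodata_propagates(self, grid3):
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = True
        layer = RasterLayer("s", grid3, np.where(mask, 0, 0.9), mask)
        out = binarize_map(layer, 0.5)
        assert out.mask[0, 0] and not out.presence[0, 0]


class TestConsensus:
    def test_seven_of_ten_votes_is_070(self, grid3):
        maps = [bmap(grid3, np.full((3, 3), i < 7)) for i in range(10)]
        cons = consensus_fraction(maps)
        assert np.allclose(cons.fraction, 0.7)
        assert (cons.n_contributors == 10).all()

    def test_identical_maps_yield_binary_fraction(self, grid3, rng):
        p = rng.random((3, 3)) < 0.5
        cons = consensus_fraction([bmap(grid3, p)] * 5)
        assert set(np.unique(cons.fraction)) <= {0.0, 1.0}
        assert np.array_equal(cons.fraction == 1.0, p)

    def test_single_map_identity(self, grid3, rng):
        p = rng.random((3, 3)) < 0.5
        cons = consensus_fraction([bmap(grid3, p)])
        assert np.array_equal(cons.fraction.astype(bool), p)

    def test_order_invariance(self, grid3, rng):
        maps = [bmap(grid3, rng.random((3, 3)) < 0.5) for _ in range(6)]
        a = consensus_fraction(maps).fraction
        b = consensus_fraction(maps[::-1]).fraction
        assert np.array_equal(a, b)

    def test_fraction_times_contributors_is_integer(self, grid3, rng):
        maps = [bmap(grid3, rng.random((3, 3)) < 0.5) for _ in range(7)]
        cons = consensus_fraction(maps)
        counts = cons.fraction * cons.n_contributors
        assert np.allclose(counts, np.round(counts))

    def test_nodata_cells_reduce_contributors(self, grid3):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        maps = [bmap(grid3, np.ones((3, 3), bool), mask.copy()),
                bmap(grid3, np.ones((3, 3), bool))]
        cons = consensus_fraction(maps)
        assert cons.n_contributors[1, 1] == 1 and cons.n_contributors[0, 0] == 2

    def test_misaligned_maps_raise(self, grid3):
        with pytest.raises(AlignmentError):
            consensus_fraction([
                bmap(grid3, np.zeros((3, 3), bool)),
                bmap(unit_grid(4), np.zeros((4, 4), bool)),
            ])

    def test_empty_list_raises(self):
        with pytest.raises(ConsensusError):
            consensus_fraction([])


class TestLikelihood:
    @pytest.mark.parametrize("fraction,expected", [
        (0.70, True), (0.66, False), (2.0 / 3.0, False), (1.0, True),
    ])
    def test_strictly_more_than_two_thirds(self, grid3, fraction, expected):
        from aridrange.ensemble_consensus import ConsensusMap
        cons = ConsensusMap(grid3, np.full((3, 3), fraction), np.full((3, 3), 3))
        out = likelihood_binarize(cons)
        assert bool(out.presence[0, 0]) is expected

    def test_default_cutoff_is_two_thirds(self):
        assert LIKELY_CUTOFF == pytest.approx(2 / 3)

    def test_monotone_in_cutoff(self, grid3, rng):
        from aridrange.ensemble_consensus import ConsensusMap
        cons = ConsensusMap(grid3, rng.random((3, 3)), np.full((3, 3), 9))
        lo = likelihood_binarize(cons, 0.5).presence
        hi = likelihood_binarize(cons, 0.8).presence
        assert (hi <= lo).all()


class TestScenarioConsensus:
    @staticmethod
    def toy_model_and_stack(rng, n=6):
        grid = unit_grid(n)
        u = RasterLayer("u", grid, rng.normal(size=(n, n)))
        stack = RasterStack([u])
        X = pd.DataFrame({"u": u.values.ravel()})
        y = (X["u"] > 0).astype(int)
        return LogisticModel().fit(X, y), stack

    def test_one_model_one_gcm_is_that_projection(self, rng):
        model, stack = self.toy_model_and_stack(rng)
        from aridrange.sdm_learners import predict_raster
        direct = binarize_map(predict_raster(model, stack), 0.5)
        out = scenario_consensus([(model, 0.5)], [(stack, "G1")], cutoff=0.4)
        assert np.array_equal(out.presence, direct.presence)

    def test_model_invariant_to_changed_variable_keeps_map(self, rng):
        model, stack = self.toy_model_and_stack(rng)
        other = RasterLayer("v", stack.grid, rng.normal(size=stack.grid.shape))
        cur = RasterStack([stack["u"], other])
        fut = RasterStack([stack["u"], RasterLayer("v", stack.grid, other.values + 5)])
        a = scenario_consensus([(model, 0.5)], [(cur, "G")], cutoff=0.4)
        b = scenario_consensus([(model, 0.5)], [(fut, "G")], cutoff=0.4)
        assert np.array_equal(a.presence, b.presence)

    def test_contributor_count_is_models_times_gcms(self, rng):
        model, stack = self.toy_model_and_stack(rng)
        models = [(model, 0.3), (model, 0.5), (model, 0.7)]
        stacks = [(stack, f"G{i}") for i in range(7)]
        out = scenario_consensus(models, stacks)
        assert len(out.provenance) == 21

    def test_empty_selection_raises(self, rng):
        _, stack = self.toy_model_and_stack(rng)
        with pytest.raises(ConsensusError, match="no consensus possible"):
            scenario_consensus([], [(stack, "G")])


class TestImportance:
    def test_ignored_variable_has_zero_importance(self, logit_design):
        X, y = logit_design
        m = LogisticModel().fit(X, y)
        m.coef_all_[2] = 0.0  # silence variable "v"
        rec = variable_importance(m, X, "v", seed=0)
        assert rec.importance == pytest.approx(0.0, abs=1e-12)
        assert len(rec.values) == 3  # default shuffle count

    def test_generating_variable_outranks_noise(self, rng):
        n = 1000
        X = pd.DataFrame({"signal": rng.normal(size=n), "noise": rng.normal(size=n)})
        y = rng.binomial(1, 1 / (1 + np.exp(-2.5 * X["signal"])))
        m = LogisticModel().fit(X, y)
        for seed in range(5):
            imp_s = variable_importance(m, X, "signal", seed=seed).importance
            imp_n = variable_importance(m, X, "noise", seed=seed).importance
            assert imp_s > imp_n

    def test_unknown_variable_raises(self, logit_design):
        X, y = logit_design
        m = LogisticModel().fit(X, y)
        with pytest.raises(KeyError):
            variable_importance(m, X, "nope")

    def test_constant_predictions_recorded_as_zero(self, logit_design, caplog):
        X, y = logit_design

        class Flat:
            feature_names_in_ = list(X.columns)
            n_features_in_ = 2

            def predict_suitability(self, X):
                return np.full(len(X), 0.5)

        with caplog.at_level("WARNING"):
            rec = variable_importance(Flat(), X, "u")
        assert rec.importance == 0.0
        assert "constant" in caplog.text


def test_scenario_tag_current_carries_no_rcp():
    with pytest.raises(ValueError):
        ScenarioTag(period="current", rcp="RCP4.5")
    assert ScenarioTag(period="2050s", rcp="RCP8.5", gcm="X").label() == "2050s_RCP8.5_X"
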