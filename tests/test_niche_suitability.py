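"""Collinearity filtering, presence-background modelling, AUC, jackknife,
classification and Jaccard overlap — against brute-force oracles where the
statistic admits one."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cimexdyn import (
    BinaryRaster,
    CovariateStack,
    OccurrenceSet,
    SuitabilityRaster,
    binarize,
    classify_suitability,
    co_suitability_map,
    jaccard_index,
    jackknife_importance,
    pearson_collinearity_filter,
    predict_suitability,
    read_ascii_grid,
    roc_auc,
    subsample_ensemble,
    train_suitability_model,
    write_ascii_grid,
)
from cimexdyn.niche_suitability import _presence_cells


def brute_force_auc(presence, background):
    """O(n*m) pair count; the independent oracle for roc_auc."""
    wins = ties = 0
    for p in presence:
        for b in background:
            if p > b:
                wins += 1
            elif p == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(presence) * len(background))


def brute_force_jaccard(u_mask, v_mask):
    inter = union = 0
    for uu, vv in zip(u_mask.ravel(), v_mask.ravel()):
        inter += bool(uu and vv)
        union += bool(uu or vv)
    return inter / union


def raster(values, **kw):
    values = np.asarray(values, dtype=float)
    return SuitabilityRaster(values=values, nodata_mask=np.zeros_like(values, bool), **kw)


class TestCollinearityFilter:
    def test_duplicate_layer_dropped(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(20, 20))
        stack = CovariateStack({"a": base, "b": base.copy(), "c": rng.normal(size=(20, 20))})
        retained = pearson_collinearity_filter(stack, threshold=0.7)
        assert len(retained) == 2 and "c" in retained

    def test_independent_layers_all_retained(self):
        rng = np.random.default_rng(1)
        stack = CovariateStack({f"l{k}": rng.normal(size=(40, 40)) for k in range(5)})
        cols = np.stack([v.ravel() for v in stack.layers.values()])
        r = np.abs(np.corrcoef(cols))
        np.fill_diagonal(r, 0)
        assert r.max() < 0.7  # verify the premise directly
        assert pearson_collinearity_filter(stack, threshold=0.7) == list(stack.names)

    def test_single_layer_retained(self):
        stack = CovariateStack({"only": np.random.default_rng(2).normal(size=(15, 15))})
        assert pearson_collinearity_filter(stack) == ["only"]

    def test_constant_layer_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        stack = CovariateStack({"flat": np.ones((12, 12)), "x": rng.normal(size=(12, 12))})
        with caplog.at_level("WARNING"):
            retained = pearson_collinearity_filter(stack)
        assert retained == ["x"]
        assert any("flat" in rec.message for rec in caplog.records)

    def test_bad_threshold_rejected(self):
        stack = CovariateStack({"x": np.random.default_rng(4).normal(size=(12, 12))})
        with pytest.raises(ValueError):
            pearson_collinearity_filter(stack, threshold=0.0)


class TestSuitabilityModel:
    def test_scores_track_planted_covariate(self, planted_stack):
        stack, _, occ = planted_stack
        model = train_suitability_model(stack, occ, seed=0)
        pred = predict_suitability(model, stack)
        r = np.corrcoef(pred.values.ravel(), stack.layers["temp"].ravel())[0, 1]
        assert r > 0.5

    def test_presence_cells_outscore_background(self, planted_stack):
        stack, _, occ = planted_stack
        model = train_suitability_model(stack, occ, seed=0)
        pred = predict_suitability(model, stack)
        cells = _presence_cells(stack, occ)
        assert pred.values[cells[:, 0], cells[:, 1]].mean() > pred.values.mean()

    def test_degenerate_single_cell_occurrences_rejected(self, planted_stack):
        stack, _, _ = planted_stack
        occ = OccurrenceSet(points=np.tile([[5.5, 5.5]], (12, 1)))
        with pytest.raises(ValueError):
            train_suitability_model(stack, occ, seed=0)

    def test_background_equal_presences_gives_chance_auc(self, planted_stack):
        stack, _, occ = planted_stack
        cells = _presence_cells(stack, occ)
        model = train_suitability_model(stack, occ, background_cells=cells)
        scores = model.score_cells(stack, cells)
        assert roc_auc(scores, scores) == 0.5

    def test_prediction_invariant_to_layer_order(self, planted_stack):
        stack, _, occ = planted_stack
        model = train_suitability_model(stack, occ, seed=0)
        permuted = CovariateStack(
            {n: stack.layers[n] for n in reversed(stack.names)},
            stack.nodata_mask, stack.cell_size, stack.origin,
        )
        assert np.array_equal(
            predict_suitability(model, stack).values,
            predict_suitability(model, permuted).values,
        )

    def test_missing_layer_named_in_error(self, planted_stack):
        stack, _, occ = planted_stack
        model = train_suitability_model(stack, occ, seed=0)
        partial = stack.subset(["temp", "humidity"])
        with pytest.raises(ValueError, match="noise_a"):
            predict_suitability(model, partial)

    def test_nodata_propagates(self, planted_stack):
        stack, _, occ = planted_stack
        model = train_suitability_model(stack, occ, seed=0)
        mask = np.zeros(stack.shape, bool)
        mask[:10] = True
        masked = CovariateStack(dict(stack.layers), mask, stack.cell_size, stack.origin)
        pred = predict_suitability(model, masked)
        assert pred.nodata_mask[:10].all()
        assert (pred.values[:10] == 0).all()


class TestEnsemble:
    def test_determinism_and_mean_of_one(self, planted_stack):
        stack, _, occ = planted_stack
        e1, a1 = subsample_ensemble(stack, occ, n_reps=1, seed=42)
        e2, a2 = subsample_ensemble(stack, occ, n_reps=1, seed=42)
        assert np.array_equal(e1.values, e2.values)
        assert a1 == a2

    def test_planted_signal_reaches_high_test_auc(self, planted_stack):
        stack, _, occ = planted_stack
        _, aucs = subsample_ensemble(stack, occ, seed=0)
        assert len(aucs) == 3
        assert all(a > 0.8 for a in aucs)

    def test_empty_split_rejected(self, planted_stack):
        stack, _, _ = planted_stack
        occ = OccurrenceSet(points=np.array([[5.5, 5.5], [10.5, 10.5]]))
        with pytest.raises(ValueError):
            subsample_ensemble(stack, occ, train_frac=0.999, n_reps=1, seed=0)


class TestRocAuc:
    def test_complete_separation(self):
        assert roc_auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_tie_symmetry(self):
        assert roc_auc([0.3, 0.7], [0.3, 0.7]) == 0.5

    def test_hand_counted_pairs(self):
        assert roc_auc([0.9, 0.4], [0.5, 0.1]) == 0.75

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [0.5])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        p=st.lists(st.sampled_from([k / 10 for k in range(11)]), min_size=1, max_size=40),
        b=st.lists(st.sampled_from([k / 10 for k in range(11)]), min_size=1, max_size=40),
    )
    def test_matches_brute_force_with_ties(self, p, b):
        assert roc_auc(p, b) == brute_force_auc(p, b)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30, unique=True),
        b=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30, unique=True),
    )
    def test_complement_identity_without_ties(self, p, b):
        if set(p) & set(b):
            return
        assert roc_auc(p, b) + roc_auc(b, p) == pytest.approx(1.0, abs=1e-12)

    def test_cross_check_against_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        p, b = rng.random(50), rng.random(80)
        expected = roc_auc_score(np.r_[np.ones(50), np.zeros(80)], np.r_[p, b])
        assert roc_auc(p, b) == pytest.approx(expected, abs=1e-12)


class TestJackknife:
    def test_planted_layer_ranks_first(self, planted_stack):
        stack, _, occ = planted_stack
        imp = jackknife_importance(stack, occ, seed=0)
        assert imp.top_variable() == "temp"
        assert set(imp.auc_only) == set(stack.names)

    def test_duplicated_signal_layer_is_redundant(self, planted_stack):
        stack, _, occ = planted_stack
        dup = CovariateStack(
            {**stack.layers, "temp_copy": stack.layers["temp"].copy()},
            stack.nodata_mask, stack.cell_size, stack.origin,
        )
        imp = jackknife_importance(dup, occ, seed=0)
        assert abs(imp.auc_without["temp"] - imp.auc_without["temp_copy"]) < 0.05

    def test_all_noise_stack_near_chance(self):
        rng = np.random.default_rng(9)
        hits = []
        for seed in range(5):
            stack = CovariateStack({f"n{k}": rng.normal(size=(30, 30)) for k in range(3)},
                                   origin=(0.0, 30.0))
            pts = np.stack([rng.uniform(0, 30, 120), rng.uniform(0, 30, 120)], axis=1)
            occ = OccurrenceSet(points=pts)
            imp = jackknife_importance(stack, occ, seed=seed)
            hits.extend(imp.auc_only.values())
        assert np.mean(np.abs(np.array(hits) - 0.5) < 0.1) > 0.8

    def test_single_layer_rejected(self, planted_stack):
        stack, _, occ = planted_stack
        with pytest.raises(ValueError):
            jackknife_importance(stack.subset(["temp"]), occ, seed=0)


class TestClassification:
    @pytest.mark.parametrize(
        "score,code", [(0.0, 0), (0.19, 0), (0.2, 1), (0.4, 2), (0.59, 2), (0.79, 3), (0.8, 4), (1.0, 4)]
    )
    def test_equal_interval_breakpoints(self, score, code):
        out = classify_suitability(raster([[score]]))
        assert out.codes[0, 0] == code

    def test_monotone_in_score(self):
        scores = np.linspace(0, 1, 101)[None, :]
        codes = classify_suitability(raster(scores)).codes[0]
        assert (np.diff(codes) >= 0).all()

    def test_nodata_preserved(self):
        r = SuitabilityRaster(values=np.array([[0.5, 0.9]]), nodata_mask=np.array([[True, False]]))
        out = classify_suitability(r)
        assert out.codes[0, 0] == -1 and out.codes[0, 1] == 4


class TestBinarizeAndJaccard:
    def test_binarize_threshold_convention(self):
        out = binarize(raster([[0.1, 0.4, 0.7]]), threshold=0.4)
        assert out.mask.tolist() == [[False, True, True]]

    def test_binarize_extremes(self):
        r = raster([[0.3, 0.6]])
        assert binarize(r, threshold=0.01).mask.all()
        assert not binarize(r, threshold=0.9).mask.any()

    def test_jaccard_identity_disjoint_and_hand_count(self):
        def braster(mask):
            mask = np.asarray(mask, bool)
            return BinaryRaster(mask=mask, nodata_mask=np.zeros_like(mask))

        u = braster([[1, 1, 0], [1, 1, 0], [0, 0, 0]])
        v = braster([[1, 1, 1], [0, 0, 0], [0, 0, 0]])
        assert jaccard_index(u, u) == 1.0
        assert jaccard_index(u, braster(~u.mask & np.array([[0,0,1],[0,0,1],[1,1,1]], bool))) == 0.0
        assert jaccard_index(u, v) == pytest.approx(0.4)  # |U∩V|=2, |U∪V|=5

    def test_empty_union_rejected(self):
        empty = BinaryRaster(mask=np.zeros((2, 2), bool), nodata_mask=np.zeros((2, 2), bool))
        with pytest.raises(ValueError):
            jaccard_index(empty, empty)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_matches_brute_force_and_is_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        shape = (rng.integers(1, 21), rng.integers(1, 21))
        u = BinaryRaster(mask=rng.random(shape) < 0.4, nodata_mask=np.zeros(shape, bool))
        v = BinaryRaster(mask=rng.random(shape) < 0.4, nodata_mask=np.zeros(shape, bool))
        if not (u.mask.any() or v.mask.any()):
            return
        j = jaccard_index(u, v)
        assert j == brute_force_jaccard(u.mask, v.mask)
        assert j == jaccard_index(v, u)
        assert 0.0 <= j <= 1.0
        assert (j == 1.0) == np.array_equal(u.mask, v.mask)


class TestCoSuitability:
    def test_self_overlap_is_identity(self):
        r = raster([[0.1, 0.5], [0.9, 0.3]])
        overlap, j = co_suitability_map(r, r)
        assert j == 1.0
        assert np.array_equal(overlap.mask, binarize(r).mask)

    def test_complement_has_empty_overlap(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.01, 0.99, size=(10, 10))
        a = raster(vals)
        b = raster(1.0 - vals)
        overlap, j = co_suitability_map(a, b, threshold=0.5)
        assert not overlap.mask.any()
        assert j == 0.0

    def test_overlap_subset_of_each_map(self):
        rng = np.random.default_rng(6)
        a = raster(rng.random((12, 12)))
        b = raster(rng.random((12, 12)))
        overlap, _ = co_suitability_map(a, b)
        assert not (overlap.mask & ~binarize(a).mask).any()
        assert not (overlap.mask & ~binarize(b).mask).any()

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            co_suitability_map(raster([[0.5]]), raster([[0.5]], cell_size=2.0))


class TestRasterIO:
    def test_ascii_grid_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        vals = rng.random((7, 5))
        mask = rng.random((7, 5)) < 0.2
        r = SuitabilityRaster(values=np.where(mask, 0, vals), nodata_mask=mask,
                              cell_size=0.5, origin=(10.0, 20.0))
        path = tmp_path / "r.asc"
        write_ascii_grid(r, path)
        back = read_ascii_grid(path)
        assert np.array_equal(back.nodata_mask, mask)
        assert np.allclose(back.values[~mask], r.values[~mask])
        assert back.cell_size == 0.5 and back.origin == (10.0, 20.0)

    def test_occurrence_csv_and_geojson_round_trip(self, tmp_path):
        occ = OccurrenceSet(points=np.array([[1.5, 2.5], [3.5, 4.5]]), species_label="sp")
        occ.to_csv(tmp_path / "occ.csv")
        occ.to_geojson(tmp_path / "occ.geojson")
        for back in (
            OccurrenceSet.from_csv(tmp_path / "occ.csv"),
            OccurrenceSet.from_geojson(tmp_path / "occ.geojson"),
        ):
            assert back.species_label == "sp"
            assert np.allclose(back.points, occ.points)
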