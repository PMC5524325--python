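import numpy as np
import pandas as pd
import pytest

from pamonitor import (
    GridGeometry,
    PREDICTOR_CLASSES,
    PredictorStack,
    SuitabilityMap,
    TooFewPresencesError,
    Undefined,
    boyce_index,
    build_ensemble,
    build_modelling_table,
    evaluate_model,
    fit_and_predict,
    make_splits,
    plan_experiment,
    select_best_level,
)
from pamonitor.sdm import EvalScores, get_learner


def occ_frame(rows):
    return pd.DataFrame(rows, columns=["species", "x", "y", "year", "presence"])


def predictor_frame(points, radius=500, rng=None):
    rng = rng or np.random.default_rng(0)
    data = {"x": [p[0] for p in points], "y": [p[1] for p in points]}
    for acr in PREDICTOR_CLASSES:
        data[f"{acr}_{radius}"] = rng.uniform(0, 60, len(points))
    return pd.DataFrame(data)


class TestModellingTable:
    def test_disjoint_species_backgrounds_are_the_other_points(self):
        pts_a = [(100.0 * i, 500.0) for i in range(12)]
        pts_b = [(100.0 * i, 900.0) for i in range(15)]
        occ = occ_frame(
            [("A", x, y, 2001, 1) for x, y in pts_a]
            + [("B", x, y, 2001, 1) for x, y in pts_b]
        )
        table = build_modelling_table(
            occ, predictor_frame(pts_a + pts_b), "A", 2001, 500
        )
        assert table.n_presences == 12
        assert table.n_backgrounds == 15
        bg = table.frame[table.frame.response == 0]
        assert set(zip(bg.x, bg.y)) == set(pts_b)

    def test_shared_location_counts_only_as_presence(self):
        shared = (500.0, 500.0)
        pts_a = [(100.0 * i, 100.0) for i in range(11)] + [shared]
        pts_b = [(100.0 * i, 900.0) for i in range(5)] + [shared]
        occ = occ_frame(
            [("A", x, y, 2001, 1) for x, y in pts_a]
            + [("B", x, y, 2001, 1) for x, y in pts_b]
        )
        table = build_modelling_table(
            occ, predictor_frame(list(set(pts_a + pts_b))), "A", 2001, 500
        )
        assert table.n_presences == 12
        assert table.n_backgrounds == 5  # shared location excluded

    def test_seven_species_background_set_arithmetic(self):
        rng = np.random.default_rng(4)
        species = [f"S{i}" for i in range(7)]
        rows = []
        all_pts = [(float(i * 50), float(j * 50)) for i in range(20) for j in range(20)]
        pts_by_sp = {}
        for sp in species:
            idx = rng.choice(len(all_pts), size=40, replace=False)
            pts_by_sp[sp] = [all_pts[i] for i in idx]
            rows += [(sp, x, y, 2001, 1) for x, y in pts_by_sp[sp]]
        occ = occ_frame(rows)
        ptab = predictor_frame(all_pts)
        for sp in species:
            table = build_modelling_table(occ, ptab, sp, 2001, 500)
            # oracle: brute-force set arithmetic on the point lists
            others = set().union(
                *(set(pts_by_sp[o]) for o in species if o != sp)
            ) - set(pts_by_sp[sp])
            assert table.n_backgrounds == len(others)

    def test_too_few_presences_is_typed_rejection(self):
        pts_a = [(100.0 * i, 100.0) for i in range(5)]
        pts_b = [(100.0 * i, 900.0) for i in range(20)]
        occ = occ_frame(
            [("A", x, y, 2001, 1) for x, y in pts_a]
            + [("B", x, y, 2001, 1) for x, y in pts_b]
        )
        with pytest.raises(TooFewPresencesError) as err:
            build_modelling_table(occ, predictor_frame(pts_a + pts_b), "A", 2001, 500)
        assert err.value.count == 5


class TestSplits:
    def make_table(self, n_pres=30, n_bg=70):
        pts = [(float(i), 0.0) for i in range(n_pres + n_bg)]
        occ = occ_frame(
            [("A", x, y, 2001, 1) for x, y in pts[:n_pres]]
            + [("B", x, y, 2001, 1) for x, y in pts[n_pres:]]
        )
        return build_modelling_table(
            occ, predictor_frame(pts), "A", 2001, 500, min_presences=5
        )

    def test_split_sizes_stratified(self):
        table = self.make_table()
        plans = make_splits(table, frac=0.7, n_rep=5, seed=1)
        y = table.frame["response"].to_numpy()
        for plan in plans:
            assert len(plan.calibration) == 70
            assert len(plan.validation) == 30
            assert y[plan.calibration].sum() == 21  # 70% of 30 presences
            assert np.intersect1d(plan.calibration, plan.validation).size == 0
            assert len(plan.calibration) + len(plan.validation) == 100

    def test_thirty_replicates_nearly_all_distinct(self):
        table = self.make_table()
        plans = make_splits(table, n_rep=30, seed=3)
        unique = {tuple(p.calibration) for p in plans}
        assert len(unique) >= 29

    def test_seed_determinism(self):
        table = self.make_table()
        a = make_splits(table, n_rep=4, seed=9)
        b = make_splits(table, n_rep=4, seed=9)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.calibration, pb.calibration)

    def test_tiny_class_rejected(self):
        table = self.make_table()
        table.frame = table.frame[table.frame.response == 0].iloc[:5].assign(response=[0, 0, 0, 0, 1])
        with pytest.raises(ValueError):
            make_splits(table)


class TestLearners:
    def test_sre_minmax_box_definition(self):
        sre = get_learner(("sre", {"percentiles": (0, 100)}))
        x = np.array([[1.0, 5.0], [3.0, 7.0], [2.0, 6.0], [10.0, 1.0]])
        y = np.array([1, 1, 1, 0])
        sre.fit(x, y)
        test = np.array([[2.0, 6.0], [1.0, 5.0], [3.5, 6.0], [2.0, 4.9]])
        np.testing.assert_array_equal(sre.predict(test), [1.0, 1.0, 0.0, 0.0])

    def test_sre_single_presence_degenerates_to_point(self):
        sre = get_learner(("sre", {"percentiles": (0, 100)}))
        x = np.array([[2.0, 3.0], [9.0, 9.0]])
        sre.fit(x, np.array([1, 0]))
        np.testing.assert_array_equal(sre.predict(np.array([[2.0, 3.0], [2.0, 3.1]])), [1.0, 0.0])

    def test_logistic_recovers_coefficient_signs(self):
        """Known generative coefficients with |coeff| > 0.5 on standardized
        predictors must come back with the right signs at n = 500."""
        rng = np.random.default_rng(17)
        n = 500
        x = rng.normal(size=(n, 4))
        true = np.array([1.5, -2.0, 0.8, 0.0])
        p = 1 / (1 + np.exp(-(x @ true)))
        y = (rng.random(n) < p).astype(int)
        learner = get_learner("logistic").fit(x, y)
        coef = learner.coefficients
        for j, t in enumerate(true):
            if abs(t) > 0.5:
                assert np.sign(coef[j]) == np.sign(t)

    def test_unknown_learner_rejected(self):
        with pytest.raises(KeyError):
            get_learner("gradient_unicorn")


class TestEvaluate:
    def test_perfect_separation(self):
        truth = np.array([0] * 50 + [1] * 50)
        pred = np.concatenate([np.linspace(0, 0.4, 50), np.linspace(0.6, 1, 50)])
        scores = evaluate_model(pred, truth)
        assert scores.auc == 1.0
        assert scores.tss == pytest.approx(1.0)
        assert scores.kappa == pytest.approx(1.0)

    def test_random_predictions_auc_half(self):
        rng = np.random.default_rng(23)
        truth = rng.integers(0, 2, 1000)
        pred = rng.random(1000)
        assert evaluate_model(pred, truth).auc == pytest.approx(0.5, abs=0.05)

    def test_auc_rank_invariance(self):
        rng = np.random.default_rng(5)
        truth = rng.integers(0, 2, 200)
        pred = rng.random(200)
        a = evaluate_model(pred, truth).auc
        b = evaluate_model(pred**3 * 0.5, truth).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate_model(np.array([0.1, 0.9]), np.array([1, 1]))


class TestBoyce:
    def test_strictly_increasing_pe_gives_one(self):
        land = np.repeat(np.linspace(0.0, 1.0, 200), 5)
        # presence density rising steeply with suitability -> P/E strictly up
        reps = np.arange(200) ** 2 // 150 + 1
        pres = np.repeat(np.linspace(0.0, 1.0, 200), reps)
        assert boyce_index(pres, land) == pytest.approx(1.0)

    def test_rank_reversal_antisymmetry(self):
        rng = np.random.default_rng(3)
        land = rng.random(2000)
        pres = rng.choice(land, 300) ** 0.5
        b = boyce_index(pres, land)
        b_rev = boyce_index(1 - pres, 1 - land)
        assert b_rev == pytest.approx(-b, abs=1e-9)

    def test_constant_landscape_is_typed_undefined(self):
        out = boyce_index(np.full(20, 0.5), np.full(200, 0.5))
        assert isinstance(out, Undefined)

    def test_affine_transform_invariance_and_nonlinear_sign(self):
        """Affine rescaling leaves windows (hence the score) unchanged;
        nonlinear monotone transforms only move window boundaries, so a
        clearly informative model stays clearly informative."""
        rng = np.random.default_rng(11)
        land = rng.random(3000)
        pres = rng.choice(land, 400, p=land / land.sum())
        b1 = boyce_index(pres, land)
        b_affine = boyce_index(0.3 * pres + 0.1, 0.3 * land + 0.1)
        assert b_affine == pytest.approx(b1, abs=1e-9)
        b_sq = boyce_index(pres**2, land**2)
        assert b_sq > 0.4 and b1 > 0.4

    def test_input_size_preconditions(self):
        with pytest.raises(ValueError):
            boyce_index(np.random.random(5), np.random.random(500))
        with pytest.raises(ValueError):
            boyce_index(np.random.random(50), np.random.random(50))


def tiny_map(values, species="A", year=2001):
    values = np.asarray(values, dtype=float)
    geom = GridGeometry(0, values.shape[0] * 500.0, 500.0, *values.shape)
    return SuitabilityMap(values, geom, species, year)


def scores_with(tss):
    return EvalScores(auc=0.9, tss=tss, kappa=0.5, tss_threshold=0.5, kappa_threshold=0.5)


class TestEnsemble:
    def test_equal_scores_give_simple_mean(self):
        a = tiny_map([[0.2, 0.4], [0.6, 0.8]])
        b = tiny_map([[0.4, 0.6], [0.8, 1.0]])
        result = build_ensemble([(a, scores_with(0.6)), (b, scores_with(0.6))], quality_floor=0.0)
        np.testing.assert_allclose(result.map.values, [[0.3, 0.5], [0.7, 0.9]])

    def test_single_positive_weight_dominates(self):
        a = tiny_map([[0.2, 0.4], [0.6, 0.8]])
        b = tiny_map([[0.9, 0.9], [0.9, 0.9]])
        result = build_ensemble([(a, scores_with(0.5)), (b, scores_with(0.0))], quality_floor=0.0)
        np.testing.assert_allclose(result.map.values, a.values)

    def test_convexity_at_every_cell(self):
        rng = np.random.default_rng(8)
        members = [
            (tiny_map(rng.random((4, 4))), scores_with(rng.uniform(0.3, 0.9)))
            for _ in range(5)
        ]
        result = build_ensemble(members, quality_floor=0.0)
        stack = np.stack([m.values for m, _ in members])
        assert (result.map.values >= stack.min(axis=0) - 1e-12).all()
        assert (result.map.values <= stack.max(axis=0) + 1e-12).all()

    def test_floor_failure_raises_with_advice(self):
        a = tiny_map([[0.1, 0.2], [0.3, 0.4]])
        with pytest.raises(ValueError, match="floor"):
            build_ensemble([(a, scores_with(0.1))], quality_floor=0.4)


class TestRadiusSelection:
    def test_argmax_and_tie_break(self):
        assert select_best_level({500.0: 0.9, 1000.0: 0.5, 2000.0: 0.3}) == 500.0
        assert select_best_level({500.0: 0.7, 1000.0: 0.7}) == 500.0

    def test_all_undefined_rejected(self):
        with pytest.raises(ValueError):
            select_best_level({500.0: Undefined("x"), 1000.0: Undefined("y")})


def test_experiment_planner_bookkeeping():
    assert plan_experiment(10, 30, 4, 2) == 2400
    assert plan_experiment(2, 30, 3, 2) == 360
    with pytest.raises(ValueError):
        plan_experiment(0, 30, 4, 2)


def test_fit_and_predict_projects_within_unit_interval(small_landscape):
    from pamonitor import extract_at_points, focal_composition

    truth = small_landscape[2]
    rng = np.random.default_rng(1)
    pts = [(float(x), float(y)) for x, y in rng.uniform(600, 4200, size=(60, 2))]
    occ = occ_frame(
        [("A", x, y, 2001, 1) for x, y in pts[:25]]
        + [("B", x, y, 2001, 1) for x, y in pts[25:]]
    )
    ptab = extract_at_points(truth, pd.DataFrame(pts, columns=["x", "y"]), radii=(500.0,))
    table = build_modelling_table(occ, ptab, "A", 2001, 500)
    stack = focal_composition(truth, 500.0, 400.0)
    split = make_splits(table, n_rep=1, seed=0)[0]
    val_pred, smap = fit_and_predict("logistic", table, split, stack)
    assert ((val_pred >= 0) & (val_pred <= 1)).all()
    vals = smap.valid_values()
    assert ((vals >= 0) & (vals <= 1)).all()
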