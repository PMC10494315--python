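import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from geniche import sdm, synthdata
from geniche.ordination import haversine_matrix


@pytest.fixture(scope="module")
def niche_ds():
    cfg = synthdata.LandscapeConfig(
        n_sites=8, inds_per_site=10, n_loci=50, n_adaptive=10,
        seed=2, grid_dims=(40, 15),
    )
    return synthdata.simulate_dataset(cfg, n_records=34)


@pytest.fixture(scope="module")
def prepared(niche_ds):
    return sdm.prepare_occurrences(
        niche_ds.occurrences, niche_ds.grid_present,
        buffer_km=1000, n_background=400, seed=2,
    )


class TestPrepare:
    def test_one_presence_per_cell(self, niche_ds):
        from geniche.io import OccurrenceSet

        rec = niche_ds.occurrences.records
        occ2 = OccurrenceSet(pd.concat([rec, rec.iloc[:3]], ignore_index=True))
        pres, _ = sdm.prepare_occurrences(
            occ2, niche_ds.grid_present, buffer_km=1000, n_background=50, seed=0
        )
        assert pres["cell_id"].is_unique
        assert len(pres) == len(rec)

    def test_zero_buffer_extent_is_presence_cells(self, niche_ds):
        pres, bg = sdm.prepare_occurrences(
            niche_ds.occurrences, niche_ds.grid_present,
            buffer_km=0, n_background=100, seed=1,
        )
        assert set(bg["cell_id"]) <= set(pres["cell_id"])

    def test_background_within_buffer(self, niche_ds):
        pres, bg = sdm.prepare_occurrences(
            niche_ds.occurrences, niche_ds.grid_present,
            buffer_km=1000, n_background=500, seed=2,
        )
        n = len(bg)
        D = haversine_matrix(
            np.concatenate([bg["lon"], pres["lon"]]),
            np.concatenate([bg["lat"], pres["lat"]]),
        )[:n, n:]
        assert (D.min(axis=1) <= 1000 + 1e-6).all()


class TestFit:
    def test_positive_coefficient_for_positive_niche_driver(self, niche_ds, prepared):
        pres, bg = prepared
        model = sdm.maxent_fit(pres, bg, synthdata.PREDICTORS, ("linear",), 1.0)
        betas = niche_ds.truth["suitability"]["betas"]
        coefs = dict(zip(synthdata.PREDICTORS, model.coef))
        for name, beta in betas.items():
            assert np.sign(coefs[name]) == np.sign(beta)

    def test_huge_penalty_flattens_predictions(self, prepared):
        pres, bg = prepared
        model = sdm.maxent_fit(pres, bg, synthdata.PREDICTORS, ("linear", "quadratic"), 1e7)
        assert np.allclose(model.coef, 0.0, atol=1e-8)
        s = model.predict(bg)
        assert s.std() < 1e-8

    def test_background_duplication_invariance(self, prepared):
        # duplicated background halves per-point weights, so the weighted
        # likelihood (and its optimum) is unchanged; with correlated hinge
        # features the L1 optimum is numerically flat in coefficient space,
        # so agreement is asserted on predictions there
        pres, bg = prepared
        bg2 = pd.concat([bg, bg], ignore_index=True)
        m1 = sdm.maxent_fit(pres, bg, synthdata.PREDICTORS, ("linear",), 1.0)
        m2 = sdm.maxent_fit(pres, bg2, synthdata.PREDICTORS, ("linear",), 1.0)
        np.testing.assert_allclose(m1.coef, m2.coef, atol=1e-5)
        feats = ("linear", "quadratic", "hinge")
        h1 = sdm.maxent_fit(pres, bg, synthdata.PREDICTORS, feats, 1.0)
        h2 = sdm.maxent_fit(pres, bg2, synthdata.PREDICTORS, feats, 1.0)
        np.testing.assert_allclose(h1.predict(bg), h2.predict(bg), atol=1e-3)

    def test_predictions_in_unit_interval(self, prepared, niche_ds):
        pres, bg = prepared
        model = sdm.maxent_fit(pres, bg, synthdata.PREDICTORS, ("linear", "hinge"), 0.5)
        s = model.predict(niche_ds.grid_present)
        assert ((s > 0) & (s < 1)).all()


class TestMetrics:
    def test_hand_worked_auc(self):
        assert sdm.auc_score([0.9, 0.8], [0.3, 0.1]) == 1.0
        assert sdm.auc_score([0.9, 0.8], [0.85, 0.1]) == 0.75

    def test_perfect_separation_tss(self):
        tss, _ = sdm.tss_score([0.9, 0.8], [0.3, 0.1])
        assert tss == 1.0

    def test_auc_near_half_on_permuted_labels(self):
        rng = np.random.default_rng(9)
        scores = rng.uniform(size=2000)
        labels = rng.random(2000) < 0.3
        auc = sdm.auc_score(scores[labels], scores[~labels])
        assert 0.45 <= auc <= 0.55

    def test_auc_invariant_to_monotone_transforms(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.05, 0.95, 50)
        b = rng.uniform(0.05, 0.95, 200)
        base = sdm.auc_score(p, b)
        assert sdm.auc_score(np.exp(p), np.exp(b)) == pytest.approx(base)
        assert sdm.auc_score(logit(p), logit(b)) == pytest.approx(base)

    def test_p10_omission_bound(self, prepared):
        pres, bg = prepared
        model = sdm.maxent_fit(pres, bg, synthdata.PREDICTORS, ("linear",), 1.0)
        thr = sdm.p10_threshold(model.train_presence_scores)
        om = sdm.omission_rate(model.train_presence_scores, thr)
        assert om <= 0.10 + 1.0 / len(pres)

    def test_boyce_true_model_beats_shuffled(self, niche_ds, prepared):
        pres, bg = prepared
        truth = niche_ds.truth["suitability"]
        s_pres = synthdata.suitability_surface(
            sdm.EnvTable(pres, synthdata.PREDICTORS), truth
        )
        s_bg = synthdata.suitability_surface(
            sdm.EnvTable(bg, synthdata.PREDICTORS), truth
        )
        good = sdm.boyce_index(s_pres, s_bg)
        rng = np.random.default_rng(6)
        shuffled = sdm.boyce_index(rng.permutation(s_bg)[: len(s_pres)], s_bg)
        assert good > shuffled


class TestTuneAndChange:
    def test_single_candidate_returned(self, prepared):
        pres, bg = prepared
        model, board = sdm.tune_select(
            pres, bg, synthdata.PREDICTORS,
            feature_sets=(("linear",),), multipliers=(1.0,), seed=0,
        )
        assert len(board) == 1
        assert model.features == ("linear",)

    def test_bell_shaped_niche_needs_curvature(self):
        # presences concentrated at intermediate driver values
        rng = np.random.default_rng(14)
        n = 900
        df = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "lon": rng.uniform(110, 112, n),
                "lat": rng.uniform(20, 22, n),
                "driver": np.linspace(-3, 3, n),
            }
        )
        suit = np.exp(-(df["driver"] ** 2))
        idx = rng.choice(n, size=60, replace=False, p=suit / suit.sum())
        pres = df.iloc[idx]
        bg = df.sample(300, random_state=0)
        model, board = sdm.tune_select(
            pres, bg, ["driver"],
            feature_sets=(("linear",), ("linear", "quadratic"), ("linear", "hinge")),
            multipliers=(1.0,), seed=1,
        )
        assert set(model.features) & {"quadratic", "hinge"}

    def test_future_equal_present_no_change(self, niche_ds, prepared):
        pres, bg = prepared
        model = sdm.maxent_fit(pres, bg, synthdata.PREDICTORS, ("linear",), 1.0)
        ch = sdm.binarize_and_change(
            model, niche_ds.grid_present, niche_ds.grid_present, background=bg
        )
        assert np.allclose(ch["delta_s"], 0.0)
        for v in ch["range_change_pct"].values():
            assert v == 0.0

    def test_suitability_drop_gives_nonpositive_delta(self, niche_ds, prepared):
        pres, bg = prepared
        model = sdm.maxent_fit(pres, bg, synthdata.PREDICTORS, ("linear",), 1.0)
        s = model.predict(niche_ds.grid_present)
        future = niche_ds.grid_present.data.copy()
        # push every cell's linear predictor downward via the model itself
        eta = model.linear_predictor(future)
        s_half = 1.0 - np.exp(-np.exp(eta - 1.0))
        assert (s_half <= s + 1e-12).all()

    def test_range_change_arithmetic_fixture(self):
        present = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0], dtype=bool)
        future = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], dtype=bool)
        change = sdm.range_change_pct(present, future)
        assert change == pytest.approx(-33.333, abs=1e-3)
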