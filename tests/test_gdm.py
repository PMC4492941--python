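import numpy as np
import pandas as pd
import pytest

from betaregio import gdm
from betaregio.containers import OccurrenceMatrix
from betaregio.gdm import (
    GEO,
    GDMModel,
    ISplineBasis,
    SitePairTable,
    build_site_pairs,
    deviance_explained,
    transform_grid,
    variable_importance,
)


def make_sites(n, n_pred, rng, names=None):
    names = names or [f"x{i}" for i in range(n_pred)]
    return pd.DataFrame({name: rng.uniform(0, 1, n) for name in names})


def simulate_pairs(n_sites=300, coefs=None, intercept=0.1, seed=0):
    """Site-pair table whose dissimilarities come exactly from a known GDM."""
    rng = np.random.default_rng(seed)
    sites = make_sites(n_sites, 3, rng)
    basis = ISplineBasis.from_values(sites)
    coefs = coefs if coefs is not None else {"x0": [0.6, 0.3, 0.8],
                                             "x1": [0.2, 0.5, 0.1],
                                             "x2": [0.4, 0.0, 0.7]}
    ii, jj = np.triu_indices(n_sites, k=1)
    eta = np.full(ii.shape, intercept)
    for name, a in coefs.items():
        t = basis.evaluate(name, sites[name].to_numpy())
        eta += np.abs(t[ii] - t[jj]) @ np.asarray(a, dtype=float)
    d = 1.0 - np.exp(-eta)
    dm = np.zeros((n_sites, n_sites))
    dm[ii, jj] = dm[jj, ii] = d
    return SitePairTable.build(dm, sites, basis=basis), d


class TestISplineBasis:
    def test_boundary_values(self, rng):
        x = rng.uniform(-3, 5, 200)
        basis = ISplineBasis.from_values({"x": x})
        lo = basis.evaluate("x", np.array([x.min()]))
        hi = basis.evaluate("x", np.array([x.max()]))
        np.testing.assert_allclose(lo, 0.0, atol=1e-12)
        np.testing.assert_allclose(hi, 1.0, atol=1e-12)

    def test_monotone_on_dense_grid(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.normal(size=100)
            basis = ISplineBasis.from_values({"x": x})
            grid = np.linspace(x.min(), x.max(), 2000)
            vals = basis.evaluate("x", grid)
            assert (np.diff(vals, axis=0) >= -1e-12).all()

    def test_clamped_outside_range(self, rng):
        x = rng.uniform(0, 1, 50)
        basis = ISplineBasis.from_values({"x": x})
        below = basis.evaluate("x", np.array([-10.0]))
        above = basis.evaluate("x", np.array([10.0]))
        np.testing.assert_allclose(below, 0.0, atol=1e-12)
        np.testing.assert_allclose(above, 1.0, atol=1e-12)

    def test_constant_predictor_dropped_with_warning(self, rng):
        with pytest.warns(UserWarning, match="constant"):
            basis = ISplineBasis.from_values({
                "flat": np.full(20, 3.0), "ok": rng.uniform(0, 1, 20)})
        assert basis.names == ["ok"]

    def test_all_constant_rejected(self):
        with pytest.raises(gdm.DegenerateBasisError):
            with pytest.warns(UserWarning):
                ISplineBasis.from_values({"flat": np.full(10, 1.0)})


class TestSitePairTable:
    def test_pair_combinatorics(self, rng):
        sites = make_sites(10, 2, rng)
        dm = np.clip((rng.random((10, 10)) + 0.1) / 1.2, 0, 1)
        dm = 0.5 * (dm + dm.T)
        np.fill_diagonal(dm, 0.0)
        pairs = SitePairTable.build(dm, sites)
        assert pairs.n_pairs == 45

    def test_empty_assemblage_sites_excluded(self, rng):
        n = 8
        vals = (rng.random((n, 6)) < 0.5).astype(np.uint8)
        vals[:, 0] = 1  # every site occupied ...
        vals[3] = 0     # ... except this one
        occ = OccurrenceMatrix(
            site_id=np.array([f"s{i}" for i in range(n)]),
            lon=rng.uniform(0, 1, n), lat=rng.uniform(0, 1, n),
            species=[f"sp{i}" for i in range(6)], values=vals)
        sites = make_sites(n, 2, rng)
        sites.insert(0, "site_id", occ.site_id)
        with pytest.warns(UserWarning, match="empty"):
            from betaregio.turnover import turnover_matrix

            turn = turnover_matrix(occ)
        pairs = build_site_pairs(occ, sites, turn)
        assert pairs.n_pairs == 7 * 6 // 2

    def test_pair_differences_match_independent_recomputation(self, rng):
        sites = make_sites(12, 2, rng)
        dm = np.zeros((12, 12))
        dm[np.triu_indices(12, 1)] = rng.uniform(0, 1, 66)
        dm = dm + dm.T
        pairs = SitePairTable.build(dm, sites)
        ii, jj = pairs.pair_idx.T
        for name in sites.columns:
            t = pairs.basis.evaluate(name, sites[name].to_numpy())
            np.testing.assert_allclose(
                pairs.X[:, pairs.blocks[name]], np.abs(t[ii] - t[jj]), atol=1e-12)

    def test_mismatched_orderings_rejected(self, rng):
        sites = make_sites(5, 2, rng)
        with pytest.raises(ValueError, match="mismatch"):
            SitePairTable.build(np.zeros((6, 6)), sites)


class TestFit:
    def test_noiseless_self_consistency(self):
        pairs, d = simulate_pairs()
        model = gdm.fit(pairs)
        assert deviance_explained(model) > 99.0
        mu = model.fitted(pairs)
        assert np.corrcoef(mu, d)[0, 1] > 0.99

    def test_permuted_response_explains_nothing(self):
        pairs, d = simulate_pairs()
        rng = np.random.default_rng(42)
        shuffled = SitePairTable(
            d=rng.permutation(pairs.d), X=pairs.X, blocks=pairs.blocks,
            basis=pairs.basis, geo_knots=pairs.geo_knots,
            pair_idx=pairs.pair_idx, weights=pairs.weights)
        model = gdm.fit(shuffled)
        assert deviance_explained(model) < 2.0

    def test_constant_response_closed_form(self, rng):
        sites = make_sites(30, 2, rng)
        dbar = 0.37
        dm = np.full((30, 30), dbar)
        np.fill_diagonal(dm, 0.0)
        pairs = SitePairTable.build(dm, sites)
        model = gdm.fit(pairs)
        assert sum(v.sum() for v in model.coefs.values()) < 1e-4
        assert model.intercept == pytest.approx(-np.log(1 - dbar), abs=1e-3)
        # the intercept-only model is already perfect: null deviance vanishes
        # and deviance explained is undefined
        assert model.D_null == pytest.approx(0.0, abs=1e-9)
        with pytest.raises(ValueError, match="undefined"):
            deviance_explained(model)

    def test_pure_noise_predictor_changes_little(self):
        # >= 1000 pairs: 50 sites -> 1225 pairs
        pairs, d = simulate_pairs(n_sites=50, seed=3)
        base = deviance_explained(gdm.fit(pairs))
        rng = np.random.default_rng(99)
        sites_noise = pd.DataFrame({"noise": rng.uniform(0, 1, 50)})
        basis_n = ISplineBasis.from_values(sites_noise)
        t = basis_n.evaluate("noise", sites_noise["noise"].to_numpy())
        ii, jj = pairs.pair_idx.T
        X = np.concatenate([pairs.X, np.abs(t[ii] - t[jj])], axis=1)
        blocks = dict(pairs.blocks)
        blocks["noise"] = slice(pairs.X.shape[1], pairs.X.shape[1] + 3)
        knots = dict(pairs.basis.knots)
        knots["noise"] = basis_n.knots["noise"]
        bigger = SitePairTable(
            d=pairs.d, X=X, blocks=blocks, basis=ISplineBasis(knots),
            geo_knots=None, pair_idx=pairs.pair_idx, weights=pairs.weights)
        augmented = deviance_explained(gdm.fit(bigger))
        assert augmented - base < 1.0

    def test_lbfgs_and_irls_agree(self):
        pairs, _ = simulate_pairs(n_sites=60, seed=7)
        m1 = gdm.fit(pairs, method="lbfgs")
        m2 = gdm.fit(pairs, method="irls")
        assert deviance_explained(m1) == pytest.approx(
            deviance_explained(m2), abs=0.5)
        np.testing.assert_allclose(m1.fitted(pairs), m2.fitted(pairs), atol=0.02)

    def test_too_few_pairs_rejected(self, rng):
        sites = make_sites(5, 2, rng)
        dm = np.zeros((5, 5))
        dm[np.triu_indices(5, 1)] = 0.5
        dm = dm + dm.T
        with pytest.raises(ValueError, match="pairs"):
            gdm.fit(SitePairTable.build(dm, sites))

    def test_coefficients_non_negative(self):
        pairs, _ = simulate_pairs(n_sites=40, seed=11)
        model = gdm.fit(pairs)
        assert model.intercept >= 0
        for v in model.coefs.values():
            assert (v >= 0).all()

    def test_deviance_explained_bounds(self):
        pairs, _ = simulate_pairs(n_sites=40, seed=13)
        model = gdm.fit(pairs)
        assert 0.0 <= deviance_explained(model) <= 100.0
        assert model.D_fit <= model.D_null


@pytest.fixture(scope="module")
def model():
    pairs, _ = simulate_pairs(n_sites=80, seed=5)
    return gdm.fit(pairs)


class TestPredict:

    def test_identical_sites_baseline(self, model):
        x = {"x0": 0.4, "x1": 0.6, "x2": 0.2}
        mu = model.predict(x, x)
        assert mu == pytest.approx(1 - np.exp(-model.intercept))

    def test_monotone_in_predictor_difference(self, model):
        base = {"x0": 0.1, "x1": 0.5, "x2": 0.5}
        deltas = np.linspace(0, 0.8, 20)
        mus = [model.predict(base, {"x0": 0.1 + d, "x1": 0.5, "x2": 0.5})
               for d in deltas]
        assert (np.diff(mus) >= -1e-12).all()

    def test_symmetric(self, model, rng):
        for _ in range(10):
            xi = {k: rng.uniform(0, 1) for k in ("x0", "x1", "x2")}
            xj = {k: rng.uniform(0, 1) for k in ("x0", "x1", "x2")}
            assert model.predict(xi, xj) == pytest.approx(model.predict(xj, xi))

    def test_missing_predictor_rejected(self, model):
        with pytest.raises(KeyError):
            model.predict({"x0": 0.1}, {"x0": 0.2})

    def test_json_roundtrip(self, model, tmp_path):
        p = tmp_path / "model.json"
        model.to_json(p)
        back = GDMModel.from_json(p)
        assert back.intercept == pytest.approx(model.intercept)
        xi = {"x0": 0.3, "x1": 0.1, "x2": 0.9}
        xj = {"x0": 0.8, "x1": 0.4, "x2": 0.2}
        assert back.predict(xi, xj) == pytest.approx(model.predict(xi, xj))


class TestImportance:
    def test_single_active_gradient_ranks_first(self):
        coefs = {"x0": [1.2, 0.8, 1.0], "x1": [0.0, 0.0, 0.0],
                 "x2": [0.0, 0.0, 0.0]}
        pairs, _ = simulate_pairs(n_sites=120, coefs=coefs, seed=21)
        model = gdm.fit(pairs)
        imp = variable_importance(pairs, model)
        assert imp.iloc[0]["predictor"] == "x0"
        others = imp[imp["predictor"] != "x0"]["delta_deviance"].max()
        assert imp.iloc[0]["delta_deviance"] >= 5 * max(others, 1e-12)

    def test_zero_coefficient_predictor_near_zero(self):
        coefs = {"x0": [1.0, 1.0, 1.0], "x1": [0.0, 0.0, 0.0],
                 "x2": [0.5, 0.5, 0.5]}
        pairs, _ = simulate_pairs(n_sites=80, coefs=coefs, seed=23)
        model = gdm.fit(pairs)
        imp = variable_importance(pairs, model).set_index("predictor")
        assert imp.loc["x1", "delta_deviance"] == pytest.approx(0.0, abs=0.5)

    def test_table_structure_and_geo_retention(self, default_env, default_survey):
        from betaregio import predictors, turnover

        pool, truth, occ = default_survey
        sites = pd.DataFrame({"site_id": occ.site_id, "lon": occ.lon, "lat": occ.lat})
        st = predictors.extract_at_sites(default_env, sites)
        sub = np.arange(80)  # subset keeps the refits quick
        occ_sub = OccurrenceMatrix(site_id=occ.site_id[sub], lon=occ.lon[sub],
                                   lat=occ.lat[sub], species=occ.species,
                                   values=occ.values[sub])
        turn = turnover.turnover_matrix(occ_sub)
        geo = predictors.geographic_distance(occ.lon[sub], occ.lat[sub])
        pairs = build_site_pairs(occ_sub, st.iloc[sub].reset_index(drop=True),
                                 turn, geo)
        model = gdm.fit(pairs)
        imp = variable_importance(pairs, model)
        assert len(imp) == 9  # all environmental predictors, geo never dropped
        assert GEO not in set(imp["predictor"])
        assert {"predictor", "delta_deviance", "percent"} <= set(imp.columns)
        assert (imp["delta_deviance"].fillna(0) >= -1e-6).all()


class TestTransformGrid:
    def test_two_cell_grid_matches_predict(self, rng):
        from betaregio.containers import GridSpec, PredictorStack

        pairs, _ = simulate_pairs(n_sites=40, seed=31)
        model = gdm.fit(pairs)
        g = GridSpec(2, 2, 0.0, 0.2, 0.0, 0.2)
        layers = {}
        for name in ("x0", "x1", "x2"):
            arr = np.full((2, 2), np.nan)
            arr[0, 0], arr[0, 1] = rng.uniform(0, 1, 2)
            layers[name] = arr
        stack = PredictorStack(grid=g, layers=layers)
        mu = transform_grid(model, stack)
        xi = {n: layers[n][0, 0] for n in layers}
        xj = {n: layers[n][0, 1] for n in layers}
        assert mu.shape == (1,)
        assert mu[0] == pytest.approx(model.predict(xi, xj))

    def test_condensed_length(self, default_env, default_survey):
        model = _grid_model(default_env, default_survey)
        mu = transform_grid(model, default_env)
        G = int(default_env.sea_mask.sum())
        assert mu.shape == (G * (G - 1) // 2,)
        assert ((mu >= 0) & (mu < 1)).all()

    def test_chunked_equals_unchunked(self, default_env, default_survey):
        model = _grid_model(default_env, default_survey)
        small = transform_grid(model, default_env, chunk_size=10_000)
        big = transform_grid(model, default_env, chunk_size=10_000_000)
        np.testing.assert_allclose(small, big, atol=1e-12)

    def test_cell_cap_enforced(self, default_env, default_survey):
        model = _grid_model(default_env, default_survey)
        with pytest.raises(ValueError, match="subsample"):
            transform_grid(model, default_env, cell_cap=100)


_model_cache = {}


def _grid_model(env, survey):
    if "m" not in _model_cache:
        from betaregio import predictors, turnover

        pool, truth, occ = survey
        sites = pd.DataFrame({"site_id": occ.site_id, "lon": occ.lon, "lat": occ.lat})
        st = predictors.extract_at_sites(env, sites)
        turn = turnover.turnover_matrix(occ)
        geo = predictors.geographic_distance(occ.lon, occ.lat)
        pairs = build_site_pairs(occ, st, turn, geo)
        _model_cache["m"] = gdm.fit(pairs)
    return _model_cache["m"]
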