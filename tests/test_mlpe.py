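"""MLPE mixed models: pair-table construction, REML/ML fits against a
dense-likelihood oracle, VIF screening, AICc competition and R-beta^2."""

import numpy as np
import pytest
from scipy import optimize as sciopt

from landgen.matrix import DistanceMatrix
from landgen.mlpe import (
    MLPE,
    aicc_compare,
    all_subsets_compare,
    build_pair_table,
    compute_vifs,
    r2_beta,
    vif_screen,
)


def make_matrices(rng, n, n_pred=2):
    labels = [f"i{k}" for k in range(n)]
    mats = {}
    for name in [f"p{j}" for j in range(n_pred)]:
        pts = rng.uniform(0, 10, (n, 3))
        mats[name] = DistanceMatrix(
            np.linalg.norm(pts[:, None] - pts[None, :], axis=-1), labels
        )
    pts = rng.uniform(0, 10, (n, 3))
    gd = DistanceMatrix(np.linalg.norm(pts[:, None] - pts[None, :], axis=-1), labels)
    return gd, mats


def simulate_mlpe(rng, n, beta, sigma_u2, sigma_e2, predictors=None):
    """Pair data from the MLPE generative model with known parameters."""
    labels = [f"i{k}" for k in range(n)]
    iu0, iu1 = np.triu_indices(n, k=1)
    m = len(iu0)
    if predictors is None:
        predictors = [rng.standard_normal(m) for _ in beta]
    u = rng.normal(0, np.sqrt(sigma_u2), n)
    y = sum(b * x for b, x in zip(beta, predictors))
    y = y + u[iu0] + u[iu1] + rng.normal(0, np.sqrt(sigma_e2), m)
    mats = {}
    for j, x in enumerate(predictors):
        full = np.zeros((n, n))
        xs = (x - x.mean()) / x.std()
        full[iu0, iu1] = np.abs(xs) + 1  # placeholder; we bypass matrices below
        mats[f"x{j}"] = full
    return labels, iu0, iu1, y, predictors


class TestPairTable:
    def test_shape_and_standardization(self, rng):
        gd, mats = make_matrices(rng, 6)
        pt = build_pair_table(gd, mats)
        assert pt.n_pairs == 15
        for name in pt.predictors:
            col = pt.data[name].to_numpy()
            assert abs(col.mean()) < 1e-12
            assert col.std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_response_not_standardized(self, rng):
        gd, mats = make_matrices(rng, 6)
        pt = build_pair_table(gd, mats)
        iu = np.triu_indices(6, k=1)
        np.testing.assert_array_equal(pt.data["gd"], gd.values[iu])

    def test_incidence_rows(self, rng):
        gd, mats = make_matrices(rng, 5)
        pt = build_pair_table(gd, mats)
        Z = pt.z_matrix()
        assert Z.shape == (10, 5)
        np.testing.assert_array_equal(Z.sum(axis=1), 2.0)
        np.testing.assert_array_equal(Z.sum(axis=0), 4.0)

    def test_label_mismatch_errors(self, rng):
        gd, mats = make_matrices(rng, 5)
        bad = DistanceMatrix(mats["p0"].values, [f"z{k}" for k in range(5)])
        with pytest.raises(ValueError, match="label"):
            build_pair_table(gd, {"p0": bad})


def dense_loglik(y, X, Z, beta, sigma_u2, sigma_e2, reml):
    """Direct multivariate-normal (RE)ML log-likelihood with an explicit
    covariance matrix; the independent oracle for the Woodbury fit."""
    m, p = X.shape
    V = sigma_u2 * (Z @ Z.T) + sigma_e2 * np.eye(m)
    Vi = np.linalg.inv(V)
    r = y - X @ beta
    ll = -0.5 * (np.linalg.slogdet(V)[1] + r @ Vi @ r + m * np.log(2 * np.pi))
    if reml:
        ll += 0.5 * p * np.log(2 * np.pi)
        ll -= 0.5 * np.linalg.slogdet(X.T @ Vi @ X)[1]
    return ll


class TestFit:
    def _fit_and_oracle(self, rng, reml):
        n = 10
        labels, iu0, iu1, y, preds = simulate_mlpe(
            rng, n, beta=[0.5], sigma_u2=0.3, sigma_e2=0.2
        )
        # build a pair table directly
        import pandas as pd

        from landgen.mlpe import PairTable

        x = (preds[0] - preds[0].mean()) / preds[0].std(ddof=0)
        pt = PairTable(pd.DataFrame({"gd": y, "x0": x}),
                       np.stack([iu0, iu1], 1), labels, "gd", ["x0"])
        res = MLPE(pt, ["x0"]).fit(reml=reml)
        model = MLPE(pt, ["x0"])
        X, Z = model.X, model.Z

        def neg(params):
            b0, b1, lu, le = params
            return -dense_loglik(y, X, Z, np.array([b0, b1]),
                                 np.exp(lu), np.exp(le), reml)

        start = np.array([res.params.iloc[0], res.params.iloc[1],
                          np.log(res.sigma_u2 + 1e-8), np.log(res.sigma_e2)])
        out = sciopt.minimize(neg, start + 0.05, method="Nelder-Mead",
                              options={"xatol": 1e-10, "fatol": 1e-12,
                                       "maxiter": 20000})
        return res, -out.fun, reml

    def test_reml_matches_dense_oracle(self, rng):
        res, oracle_ll, _ = self._fit_and_oracle(rng, reml=True)
        assert res.loglik_reml == pytest.approx(oracle_ll, abs=1e-4)

    def test_ml_matches_dense_oracle(self, rng):
        res, oracle_ll, _ = self._fit_and_oracle(rng, reml=False)
        assert res.loglik_ml == pytest.approx(oracle_ll, abs=1e-4)

    def test_intercept_only_null(self, rng):
        n = 8
        labels, iu0, iu1, y, _ = simulate_mlpe(rng, n, beta=[], sigma_u2=0.2,
                                               sigma_e2=0.1)
        import pandas as pd

        from landgen.mlpe import PairTable

        pt = PairTable(pd.DataFrame({"gd": y}), np.stack([iu0, iu1], 1),
                       labels, "gd", [])
        res = MLPE(pt, []).fit()
        # GLS intercept stays within a few SE of the sample mean
        assert res.params["intercept"] == pytest.approx(
            y.mean(), abs=4 * res.bse["intercept"] + 0.05
        )

    def test_zero_u_variance_limit_matches_ols(self, rng):
        """In the sigma_u^2 -> 0 limit the profiled ML log-likelihood
        equals the ordinary-regression closed form; the free fit can only
        do better."""
        n = 12
        labels, iu0, iu1, y, preds = simulate_mlpe(
            rng, n, beta=[0.4], sigma_u2=0.0, sigma_e2=0.25
        )
        import pandas as pd

        from landgen.mlpe import PairTable

        x = (preds[0] - preds[0].mean()) / preds[0].std(ddof=0)
        pt = PairTable(pd.DataFrame({"gd": y, "x0": x}),
                       np.stack([iu0, iu1], 1), labels, "gd", ["x0"])
        model = MLPE(pt, ["x0"])
        boundary_ll = -0.5 * model._profile(-15.0, False)[0]
        X = np.column_stack([np.ones(len(y)), x])
        bhat = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(((y - X @ bhat) ** 2).sum())
        m = len(y)
        ols_ll = -0.5 * m * (np.log(2 * np.pi * rss / m) + 1)
        assert boundary_ll == pytest.approx(ols_ll, abs=1e-4)
        res = model.fit(reml=False)
        assert res.loglik_ml >= ols_ll - 1e-8
        assert res.sigma_u2 < 0.2 * res.sigma_e2  # near the boundary

    def test_shared_individual_covariance_structure(self, rng):
        """Model-implied covariance between pairs sharing an individual is
        sigma_u^2, matched against the constructed covariance matrix."""
        n = 8
        labels, iu0, iu1, y, preds = simulate_mlpe(
            rng, n, beta=[0.3], sigma_u2=0.4, sigma_e2=0.1
        )
        import pandas as pd

        from landgen.mlpe import PairTable

        x = (preds[0] - preds[0].mean()) / preds[0].std(ddof=0)
        pt = PairTable(pd.DataFrame({"gd": y, "x0": x}),
                       np.stack([iu0, iu1], 1), labels, "gd", ["x0"])
        res = MLPE(pt, ["x0"]).fit()
        Z = pt.z_matrix()
        V = res.sigma_u2 * (Z @ Z.T) + res.sigma_e2 * np.eye(pt.n_pairs)
        share = (Z @ Z.T) == 1  # pairs sharing exactly one individual
        assert np.allclose(V[share], res.sigma_u2)
        assert np.allclose(np.diag(V), 2 * res.sigma_u2 + res.sigma_e2)

    def test_row_order_invariance(self, rng):
        n = 8
        labels, iu0, iu1, y, preds = simulate_mlpe(
            rng, n, beta=[0.3], sigma_u2=0.2, sigma_e2=0.1
        )
        import pandas as pd

        from landgen.mlpe import PairTable

        x = (preds[0] - preds[0].mean()) / preds[0].std(ddof=0)
        order = rng.permutation(len(y))
        pt1 = PairTable(pd.DataFrame({"gd": y, "x0": x}),
                        np.stack([iu0, iu1], 1), labels, "gd", ["x0"])
        pt2 = PairTable(pd.DataFrame({"gd": y[order], "x0": x[order]}),
                        np.stack([iu0[order], iu1[order]], 1), labels, "gd", ["x0"])
        r1, r2 = MLPE(pt1, ["x0"]).fit(), MLPE(pt2, ["x0"]).fit()
        assert r1.loglik_reml == pytest.approx(r2.loglik_reml, abs=1e-8)
        assert r1.params["x0"] == pytest.approx(r2.params["x0"], abs=1e-8)

    def test_rank_deficiency_errors(self, rng):
        gd, mats = make_matrices(rng, 6)
        mats["dup"] = DistanceMatrix(mats["p0"].values.copy(), gd.labels)
        pt = build_pair_table(gd, mats)
        with pytest.raises(ValueError, match="rank"):
            MLPE(pt, ["p0", "dup"])


class TestVIF:
    def test_duplicated_predictor_dropped(self, rng):
        gd, mats = make_matrices(rng, 8, n_pred=2)
        mats["dup"] = DistanceMatrix(mats["p0"].values.copy(), gd.labels)
        pt = build_pair_table(gd, mats)
        retained = vif_screen(pt, threshold=5.0)
        assert len(retained) == 2
        assert not {"p0", "dup"} <= set(retained)

    def test_orthogonal_predictors_retained_with_unit_vif(self, rng):
        gd, mats = make_matrices(rng, 10, n_pred=1)
        m = 45
        import pandas as pd

        from landgen.mlpe import PairTable

        iu0, iu1 = np.triu_indices(10, k=1)
        a = rng.standard_normal(m)
        a -= a.mean()
        b = rng.standard_normal(m)
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)  # centered, then orthogonalized
        pt = PairTable(pd.DataFrame({"gd": rng.standard_normal(m), "a": a, "b": b}),
                       np.stack([iu0, iu1], 1), gd.labels, "gd", ["a", "b"])
        vifs = compute_vifs(pt)
        assert vifs["a"] == pytest.approx(1.0, abs=1e-9)
        assert vifs["b"] == pytest.approx(1.0, abs=1e-9)
        assert vif_screen(pt) == ["a", "b"]

    def test_vif_matches_regression_closed_form(self, rng):
        """Three equicorrelated predictors: VIF = 1/(1 - R^2) from an
        independent least-squares fit."""
        import pandas as pd

        from landgen.mlpe import PairTable

        n = 12
        iu0, iu1 = np.triu_indices(n, k=1)
        m = len(iu0)
        z = rng.standard_normal(m)
        cols = {f"v{j}": 0.9 * z + np.sqrt(1 - 0.81) * rng.standard_normal(m)
                for j in range(3)}
        pt = PairTable(pd.DataFrame({"gd": rng.standard_normal(m), **cols}),
                       np.stack([iu0, iu1], 1), [f"i{k}" for k in range(n)],
                       "gd", list(cols))
        vifs = compute_vifs(pt)
        for t in cols:
            others = [o for o in cols if o != t]
            X = np.column_stack([np.ones(m)] + [cols[o] for o in others])
            yv = cols[t]
            resid = yv - X @ np.linalg.lstsq(X, yv, rcond=None)[0]
            r2 = 1 - (resid @ resid) / (((yv - yv.mean()) ** 2).sum())
            assert vifs[t] == pytest.approx(1 / (1 - r2), rel=1e-9)


class TestAICc:
    def test_worked_value(self, rng):
        """AICc = -2(-100) + 2*3 + 2*3*4/(50-3-1) = 206.5217..."""
        gd, mats = make_matrices(rng, 8, n_pred=1)
        pt = build_pair_table(gd, mats)
        res = MLPE(pt, ["p0"]).fit()
        object.__setattr__(res, "loglik_ml", -100.0)
        # res has k = 2 fixed + 2 variance = 4; force k=3 via a null fit
        null = MLPE(pt, []).fit()  # k = 1 + 2 = 3
        object.__setattr__(null, "loglik_ml", -100.0)
        assert null.aicc(n=50) == pytest.approx(200 + 6 + 24 / 46, abs=1e-4)

    def test_equal_models_share_weight(self, rng):
        gd, mats = make_matrices(rng, 8, n_pred=1)
        pt = build_pair_table(gd, mats)
        a = MLPE(pt, ["p0"]).fit()
        b = MLPE(pt, ["p0"]).fit()
        table = aicc_compare([a, b])
        np.testing.assert_allclose(table["weight"], 0.5)
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_model_weight_one(self, rng):
        gd, mats = make_matrices(rng, 8, n_pred=1)
        pt = build_pair_table(gd, mats)
        table = aicc_compare([MLPE(pt, ["p0"]).fit()])
        assert table["weight"].iloc[0] == pytest.approx(1.0)

    def test_small_n_errors(self, rng):
        gd, mats = make_matrices(rng, 8, n_pred=1)
        pt = build_pair_table(gd, mats)
        res = MLPE(pt, ["p0"]).fit()
        with pytest.raises(ValueError, match="too small"):
            res.aicc(n=4)

    def test_delta_flags(self, rng):
        gd, mats = make_matrices(rng, 10, n_pred=2)
        pt = build_pair_table(gd, mats)
        table, _ = all_subsets_compare(pt)
        assert table["supported"].iloc[0]  # best model has delta 0
        assert (table.loc[table.delta_aicc > 7, "marginal"] == False).all()  # noqa: E712


class TestR2Beta:
    def test_null_vs_null_is_zero(self, rng):
        gd, mats = make_matrices(rng, 8, n_pred=1)
        pt = build_pair_table(gd, mats)
        null = MLPE(pt, []).fit()
        assert r2_beta(null, null) == 0.0

    def test_monotone_in_effect_size(self):
        """R-beta^2 grows along a ladder of simulated effect sizes."""
        import pandas as pd

        from landgen.mlpe import PairTable

        rng = np.random.default_rng(11)
        n = 25
        iu0, iu1 = np.triu_indices(n, k=1)
        m = len(iu0)
        x = rng.standard_normal(m)
        x = (x - x.mean()) / x.std(ddof=0)
        u = rng.normal(0, 0.3, n)
        noise = rng.normal(0, 0.3, m)
        r2s = []
        for beta in (0.0, 0.2, 0.6):
            y = beta * x + u[iu0] + u[iu1] + noise
            pt = PairTable(pd.DataFrame({"gd": y, "x": x}),
                           np.stack([iu0, iu1], 1),
                           [f"i{k}" for k in range(n)], "gd", ["x"])
            r2s.append(r2_beta(MLPE(pt, ["x"]).fit(), MLPE(pt, []).fit()))
        assert r2s[0] < r2s[1] < r2s[2]

    def test_mismatched_null_errors(self, rng):
        gd, mats = make_matrices(rng, 8, n_pred=2)
        pt = build_pair_table(gd, mats)
        full = MLPE(pt, ["p0"]).fit()
        not_null = MLPE(pt, ["p1"]).fit()
        with pytest.raises(ValueError, match="intercept"):
            r2_beta(full, not_null)
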