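"""Maximum-entropy fit: analytic solutions, convex-oracle agreement,
scale identities and projection clamping."""
import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

import richstack as rs
from richstack.exceptions import ConfigurationError, InputError
from richstack.maxent import FeatureSet, Feature

from conftest import make_stack, tiny_meta


def swd_from_arrays(pres_cov: dict, bg_cov: dict) -> pd.DataFrame:
    """Assemble a minimal SWD table from per-covariate value arrays."""
    n_p = len(next(iter(pres_cov.values())))
    n_b = len(next(iter(bg_cov.values())))
    rows = {
        "species": ["sp"] * n_p + [rs.BACKGROUND_LABEL] * n_b,
        "longitude": np.zeros(n_p + n_b),
        "latitude": np.zeros(n_p + n_b),
    }
    for k in pres_cov:
        rows[k] = np.concatenate([pres_cov[k], bg_cov[k]])
    return pd.DataFrame(rows)


def proximal_gradient_oracle(F_bg, fbar, beta, n_iter=300_000, lr=0.05):
    """Independent solver for the L1-penalized maxent dual: plain proximal
    gradient (ISTA) on  logZ(lam) - lam@fbar + beta@|lam|."""
    lam = np.zeros(F_bg.shape[1])
    for _ in range(n_iter):
        eta = F_bg @ lam
        w = np.exp(eta - logsumexp(eta))
        grad = F_bg.T @ w - fbar
        lam = lam - lr * grad
        lam = np.sign(lam) * np.maximum(np.abs(lam) - lr * beta, 0.0)  # soft-threshold
    return lam


def identity_features(names):
    """Feature set passing covariates through untouched (bounds [0,1])."""
    return FeatureSet(
        features=[Feature(n, "linear", n) for n in names],
        bounds={n: (0.0, 1.0) for n in names},
    )


class TestBuildFeatures:
    def _bg(self, **cols):
        n = len(next(iter(cols.values())))
        return pd.DataFrame({"species": ["background"] * n, "longitude": 0.0,
                             "latitude": 0.0, **cols})

    def test_linear_plus_quadratic_count(self):
        fs = rs.build_features(self._bg(a=[0.0, 1.0, 2.0]))
        assert fs.n_features == 2

    def test_product_class_adds_all_pairs(self):
        fs = rs.build_features(self._bg(a=[0, 1], b=[1, 2], c=[2, 3]),
                               classes=("linear", "product"))
        assert fs.n_features == 3 + 3

    def test_constant_covariate_dropped(self):
        fs = rs.build_features(self._bg(a=[0.0, 1.0], b=[5.0, 5.0]))
        assert "b" not in fs.bounds

    def test_all_constant_is_an_error(self):
        with pytest.raises(InputError):
            rs.build_features(self._bg(a=[1.0, 1.0]))


class TestFitAnalytic:
    def test_two_cell_one_feature_closed_form(self):
        # background features {0, 1}; all presences at f=1; fixed beta=0.1.
        # Stationarity: E_q[f] = 1 - beta = 0.9  =>  lambda = ln 9.
        swd = swd_from_arrays({"f": np.ones(5)}, {"f": np.array([0.0, 1.0])})
        model = rs.fit_maxent(swd, identity_features(["f"]), betas=0.1, tol=1e-14,
                              max_iter=2000)
        assert model.lmbda[0] == pytest.approx(np.log(9.0), abs=1e-4)
        q = model.raw_scores(np.array([[0.0], [1.0]]))
        np.testing.assert_allclose(q, [0.1, 0.9], atol=1e-4)

    def test_matched_means_give_zero_weights(self):
        # presence mean equals background mean -> origin is stationary
        swd = swd_from_arrays({"f": np.array([0.0, 1.0])},
                              {"f": np.array([0.0, 1.0])})
        model = rs.fit_maxent(swd, identity_features(["f"]), betas=0.05)
        assert model.lmbda[0] == pytest.approx(0.0, abs=1e-8)

    def test_large_penalty_shrinks_to_uniform(self):
        swd = swd_from_arrays({"f": np.ones(4)}, {"f": np.array([0.0, 0.5, 1.0])})
        model = rs.fit_maxent(swd, identity_features(["f"]), betas=50.0)
        assert model.lmbda[0] == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(
            model.raw_scores(np.array([[0.0], [0.5], [1.0]])), 1 / 3, atol=1e-8
        )

    def test_no_presences_rejected(self):
        swd = swd_from_arrays({"f": np.zeros(0)}, {"f": np.array([0.0, 1.0])})
        with pytest.raises(InputError):
            rs.fit_maxent(swd, identity_features(["f"]))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_proximal_gradient_on_small_landscapes(self, seed):
        rng = np.random.default_rng(seed)
        m, n_pres = 60, 25
        cov_bg = {c: rng.uniform(0, 1, m) for c in ("a", "b")}
        cov_pr = {c: rng.uniform(0.3, 1, n_pres) for c in ("a", "b")}
        swd = swd_from_arrays(cov_pr, cov_bg)
        fs = rs.build_features(swd[swd.species == "background"])
        assert fs.n_features <= 5
        model = rs.fit_maxent(swd, fs, tol=1e-14, max_iter=5000)
        F_bg = fs.design_matrix(swd[swd.species == "background"], clamp=False)
        F_pr = fs.design_matrix(swd[swd.species != "background"], clamp=True)
        lam_star = proximal_gradient_oracle(F_bg, F_pr.mean(axis=0), model.betas)
        assert np.max(np.abs(model.lmbda - lam_star)) < 1e-3
        q_fit = model.raw_scores(F_bg)
        eta = F_bg @ lam_star
        q_star = np.exp(eta - logsumexp(eta))
        assert np.max(np.abs(q_fit - q_star)) < 1e-4

    def test_moment_matching_in_unpenalized_limit(self):
        rng = np.random.default_rng(3)
        swd = swd_from_arrays({"a": rng.uniform(0.5, 1, 30)},
                              {"a": rng.uniform(0, 1, 50)})
        fs = rs.build_features(swd[swd.species == "background"])
        F_bg = fs.design_matrix(swd[swd.species == "background"], clamp=False)
        F_pr = fs.design_matrix(swd[swd.species != "background"], clamp=True)
        for beta0 in (1.0, 0.1, 0.01, 0.001):
            model = rs.fit_maxent(swd, fs, beta0=beta0, tol=1e-14, max_iter=5000)
            q = model.raw_scores(F_bg)
            gap = np.max(np.abs(F_bg.T @ q - F_pr.mean(axis=0)))
            # at the optimum the moment gap is bounded by the penalty scale
            assert gap <= model.betas.max() + 1e-6
        assert gap < 1e-3


class TestPredict:
    def test_zero_weights_give_uniform_raw_and_half_logistic(self, meta):
        stack = make_stack(meta, {"a": np.linspace(0, 1, 20).reshape(4, 5)})
        swd = swd_from_arrays({"a": np.array([0.2, 0.8])},
                              {"a": np.array([0.2, 0.8])})
        fs = rs.build_features(swd[swd.species == "background"])
        model = rs.fit_maxent(swd, fs, betas=0.05)
        assert np.all(model.lmbda == 0)
        raw = rs.predict(model, stack, scale="raw")
        np.testing.assert_allclose(raw.values[stack.land_mask], 1 / 2, atol=1e-12)
        logi = rs.predict(model, stack, scale="logistic")
        np.testing.assert_allclose(logi.values[stack.land_mask], 0.5, atol=1e-12)

    def test_raw_sums_to_one_over_training_background(self, swd_table, feature_set):
        taxon = swd_table[swd_table.species != "background"].species.iloc[0]
        swd_t = swd_table[(swd_table.species == taxon) | (swd_table.species == "background")]
        model = rs.fit_maxent(swd_t, feature_set)
        bg = swd_table[swd_table.species == "background"]
        raw = model.score_table(bg, scale="raw")
        assert raw.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scales_are_rank_equivalent(self, swd_table, feature_set, landscape):
        taxon = swd_table[swd_table.species != "background"].species.iloc[0]
        swd_t = swd_table[(swd_table.species == taxon) | (swd_table.species == "background")]
        model = rs.fit_maxent(swd_t, feature_set)
        raw = rs.predict(model, landscape.stack, scale="raw").values
        logi = rs.predict(model, landscape.stack, scale="logistic").values
        mask = landscape.stack.land_mask
        order_raw = np.argsort(raw[mask], kind="stable")
        order_log = np.argsort(logi[mask], kind="stable")
        np.testing.assert_array_equal(order_raw, order_log)

    def test_projection_clamps_to_training_range(self, meta):
        swd = swd_from_arrays({"a": np.array([4.0, 6.0])},
                              {"a": np.array([0.0, 5.0, 10.0])})
        fs = rs.build_features(swd[swd.species == "background"])
        model = rs.fit_maxent(swd, fs)
        inside = model.score_table({"a": np.array([10.0])}, scale="raw")
        beyond = model.score_table({"a": np.array([25.0])}, scale="raw")
        assert beyond[0] == pytest.approx(inside[0])

    def test_missing_covariate_layer_raises(self, meta):
        stack = make_stack(meta, {"other": np.ones((4, 5))})
        swd = swd_from_arrays({"a": np.array([1.0])}, {"a": np.array([0.0, 2.0])})
        fs = rs.build_features(swd[swd.species == "background"])
        model = rs.fit_maxent(swd, fs)
        with pytest.raises(ConfigurationError):
            rs.predict(model, stack)

    def test_entropy_within_bounds(self, swd_table, feature_set):
        taxon = swd_table[swd_table.species != "background"].species.iloc[0]
        swd_t = swd_table[(swd_table.species == taxon) | (swd_table.species == "background")]
        model = rs.fit_maxent(swd_t, feature_set)
        assert 0.0 <= model.entropy_raw <= np.log(model.background_size)
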