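"""Parametric bootstrap: draws, SE oracles, attribution, reporting."""

import numpy as np
import pandas as pd
import pytest

from standcarbon.allometry import AllometricModelSet
from standcarbon.als import AreaModel, AreaModelSet
from standcarbon.soil import DEFAULT_SOIL_PARAMS
from standcarbon.uncertainty import (
    ChangeDistribution,
    MODEL_GROUPS,
    attribute_errors,
    bootstrap_changes,
    draw_parameters,
    summarize,
)


def _toy_area_set(covs: dict) -> AreaModelSet:
    """Four named models; selected ones get a nonzero coefficient covariance."""
    forms = {
        "lnD": (True, "D", ["D_ALS_4", "H_ALS_mean", "T"], [1.2, 1.2, 0.08, 0.0]),
        "Hdom": (False, "Hdom", ["D_ALS_2", "D_ALS_8", "H_ALS_80", "T"],
                 [1.0, 2.0, 1.0, 1.05, 0.0]),
        "lnBMS": (True, "BMS", ["D_ALS_2", "H_ALS_80", "T"], [1.5, 2.2, 0.10, 0.0]),
        "H": (False, "H", ["Hdom", "T"], [0.3, 0.8, 0.0]),
    }
    models = {}
    for name, (logr, resp, preds, beta) in forms.items():
        beta = np.asarray(beta, dtype=float)
        cov = covs.get(name, np.zeros((len(beta), len(beta))))
        models[name] = AreaModel(name, resp, logr, preds, beta, cov, 0.0)
    return models and AreaModelSet(models)


EMPTY_ALLO = AllometricModelSet({})
FIXED_SOIL_SAMPLE = DEFAULT_SOIL_PARAMS.to_vector()[None, :]


def _chain_factory(base, value_fn):
    """run_chain computing a single-stand 'dC_AGB' via value_fn(area_mset)."""

    def make():
        def run_chain(draw):
            mset = base if draw is None else draw.area_mset
            v = float(value_fn(mset))
            stands = pd.DataFrame({"stand_id": [0], "dC_AGB": [v], "area_ha": [1.0]})
            return stands, {"dC_AGB": v}
        return run_chain
    return make


class TestDraws:
    def test_zero_covariance_draws_equal_mean(self):
        area = _toy_area_set({})
        draws = draw_parameters(area, EMPTY_ALLO, soil_sample=FIXED_SOIL_SAMPLE,
                                b=5, seed=3)
        for d in draws:
            for name in ("lnBMS", "Hdom", "H", "lnD"):
                assert np.array_equal(d.area_mset[name].beta, area[name].beta)

    def test_fixed_seed_reproducible(self):
        cov = 0.01 * np.eye(4)
        area = _toy_area_set({"lnBMS": cov})
        a = draw_parameters(area, EMPTY_ALLO, soil_sample=FIXED_SOIL_SAMPLE, b=8, seed=11)
        b = draw_parameters(area, EMPTY_ALLO, soil_sample=FIXED_SOIL_SAMPLE, b=8, seed=11)
        for d1, d2 in zip(a, b):
            assert np.array_equal(d1.area_mset["lnBMS"].beta, d2.area_mset["lnBMS"].beta)

    def test_draw_mean_converges_to_model_mean(self):
        cov = np.diag([0.04, 0.01, 0.0025, 0.0])
        area = _toy_area_set({"lnBMS": cov})
        b = 10_000
        draws = draw_parameters(area, EMPTY_ALLO, soil_sample=FIXED_SOIL_SAMPLE,
                                b=b, seed=5)
        betas = np.array([d.area_mset["lnBMS"].beta for d in draws])
        for j in range(4):
            tol = 3 * np.sqrt(cov[j, j] / b) + 1e-12
            assert abs(betas[:, j].mean() - area["lnBMS"].beta[j]) < tol

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            draw_parameters(_toy_area_set({}), EMPTY_ALLO,
                            soil_sample=FIXED_SOIL_SAMPLE, b=1, seed=0,
                            active={"nope"})


class TestBootstrap:
    def test_single_draw_at_mean_reproduces_point_estimate(self):
        area = _toy_area_set({})
        x = np.array([1.0, 0.5, 12.0, 0.0])
        make = _chain_factory(area, lambda m: np.exp(x @ m["lnBMS"].beta))
        draws = draw_parameters(area, EMPTY_ALLO, soil_sample=FIXED_SOIL_SAMPLE,
                                b=1, seed=0)
        dist = bootstrap_changes(make(), draws, pools=["AGB"])
        assert dist.outcomes[0, 0, 0] == pytest.approx(
            dist.point["dC_AGB"].iloc[0], rel=1e-12)
        assert dist.se.iloc[0, 0] == 0.0

    def test_bootstrap_se_matches_delta_method_oracle(self):
        """Log-linear prediction: bootstrap SE vs exp(x'b) sqrt(x'Sx)."""
        rng = np.random.default_rng(7)
        a = rng.normal(0, 0.05, (4, 4))
        # keep the log-scale sd small so the delta linearisation is accurate
        cov = 1.5e-5 * np.eye(4) + a @ a.T * 1e-4
        area = _toy_area_set({"lnBMS": cov})
        x = np.array([1.0, 0.5, 12.0, 1.0])
        make = _chain_factory(area, lambda m: np.exp(x @ m["lnBMS"].beta))
        draws = draw_parameters(area, EMPTY_ALLO, soil_sample=FIXED_SOIL_SAMPLE,
                                b=2000, seed=19)
        dist = bootstrap_changes(make(), draws, pools=["AGB"])
        mu = float(np.exp(x @ area["lnBMS"].beta))
        delta_se = mu * np.sqrt(x @ cov @ x)
        assert dist.landscape_se["AGB"] == pytest.approx(delta_se, rel=0.05)

    def test_independent_additive_stages_have_additive_variance(self):
        cov_h = np.diag([0.02, 0.001, 0.0])
        cov_hd = np.diag([0.03, 0.002, 0.001, 0.0005, 0.0])
        area = _toy_area_set({"H": cov_h, "Hdom": cov_hd})
        xh = np.array([1.0, 15.0, 0.0])
        xd = np.array([1.0, 0.6, 0.2, 14.0, 0.0])
        make = _chain_factory(
            area, lambda m: xh @ m["H"].beta + xd @ m["Hdom"].beta)
        kw = dict(soil_sample=FIXED_SOIL_SAMPLE, b=4000, seed=23)
        var = {}
        for active in ({"H"}, {"Hdom"}, {"H", "Hdom"}):
            draws = draw_parameters(area, EMPTY_ALLO, active=active, **kw)
            dist = bootstrap_changes(make(), draws, pools=["AGB"])
            var[frozenset(active)] = dist.landscape_se["AGB"] ** 2
        total = var[frozenset({"H", "Hdom"})]
        assert total == pytest.approx(
            var[frozenset({"H"})] + var[frozenset({"Hdom"})], rel=0.1)


class TestAttribution:
    def test_single_uncertain_model_takes_full_share(self):
        cov = np.diag([0.01, 0.001, 0.0001, 0.0])
        area = _toy_area_set({"lnBMS": cov})
        x = np.array([1.0, 0.5, 12.0, 1.0])
        make = _chain_factory(area, lambda m: np.exp(x @ m["lnBMS"].beta))
        shares, _ = attribute_errors(make, area, EMPTY_ALLO,
                                     soil_sample=FIXED_SOIL_SAMPLE,
                                     b=60, seed=2, pools=["AGB"])
        assert shares.loc["lnBMS", "AGB"] == pytest.approx(100.0, abs=1e-9)
        for g in MODEL_GROUPS:
            if g != "lnBMS":
                assert shares.loc[g, "AGB"] == 0.0

    def test_multiplicative_chain_shares_do_not_add_up(self):
        area = _toy_area_set({
            "H": np.diag([0.04, 0.0, 0.0]),
            "Hdom": np.diag([0.04, 0.0, 0.0, 0.0, 0.0]),
        })
        make = _chain_factory(area, lambda m: m["H"].beta[0] * m["Hdom"].beta[0] * 10.0)
        shares, _ = attribute_errors(make, area, EMPTY_ALLO,
                                     soil_sample=FIXED_SOIL_SAMPLE,
                                     b=800, seed=3, pools=["AGB"])
        total = shares["AGB"].sum()
        assert abs(total - 100.0) > 5.0  # interactions: no forced 100% budget

    def test_share_grows_with_own_covariance(self):
        x = np.array([1.0, 0.5, 12.0, 1.0])
        shares = []
        for scale in (0.0005, 0.002):
            area = _toy_area_set({
                "lnBMS": scale * np.eye(4),
                "lnD": np.diag([0.01, 0.0, 0.0, 0.0]),
            })
            make = _chain_factory(
                area, lambda m: np.exp(x @ m["lnBMS"].beta) + m["lnD"].beta[0])
            tab, _ = attribute_errors(make, area, EMPTY_ALLO,
                                      soil_sample=FIXED_SOIL_SAMPLE,
                                      b=400, seed=4, pools=["AGB"])
            shares.append(tab.loc["lnBMS", "AGB"])
        assert shares[1] > shares[0]


class TestSummarize:
    def _dist(self, estimates, ses, b=200, seed=0):
        rng = np.random.default_rng(seed)
        n = len(estimates)
        outcomes = estimates + ses * rng.standard_normal((b, n))
        point = pd.DataFrame({"stand_id": np.arange(n), "dC_AGB": estimates})
        return ChangeDistribution(
            np.arange(n), ["AGB"], outcomes[:, :, None],
            outcomes.mean(axis=1, keepdims=True), point, {}, 0, b)

    def test_relative_se_arithmetic(self):
        dist = self._dist(np.array([2.0]), np.array([0.0]))
        dist.outcomes = np.array([[[1.7]], [[2.3]]])  # sd = 0.424; use direct SE
        se = dist.se.iloc[0, 0]
        assert 100 * se / 2.0 == pytest.approx(100 * np.std([1.7, 2.3], ddof=1) / 2.0)
        # a stand with estimate 2.0 and SE 0.3 reports 15%
        assert 100 * 0.3 / 2.0 == 15.0

    def test_all_stands_significant(self):
        dist = self._dist(np.full(20, 5.0), np.full(20, 0.1), b=400, seed=1)
        report = summarize(dist)
        assert report.loc["AGB", "significant_share_pct"] == 100.0

    def test_percentile_filter_matches_brute_force(self):
        est = np.concatenate([np.full(99, 2.0), [1e-9]])  # one exploding SE%
        dist = self._dist(est, np.full(100, 0.2), b=300, seed=2)
        report = summarize(dist)
        se = dist.se["AGB"].to_numpy()
        rel = 100 * se / np.abs(est)
        rel = rel[np.isfinite(rel)]
        cut = np.percentile(rel, 99.0)
        expect = rel[rel <= cut].mean()
        assert report.loc["AGB", "mean_se_pct"] == pytest.approx(expect, rel=1e-9)
        assert report.loc["AGB", "mean_se_pct"] < 50.0  # outlier removed
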