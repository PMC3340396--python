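"""Variation partitioning identities, lmg closed forms and brute-force
ordering oracle, and despatialized importance behaviour."""

import dataclasses
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from riverscape import partition as pt
from riverscape import synthetic as syn
from riverscape.aem import aem_basis_from_graph


def _r2(X, y):
    Xd = np.column_stack([np.ones(len(y)), np.atleast_2d(X.T).T]) \
        if np.asarray(X).size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    r = y - Xd @ beta
    tss = np.sum((y - y.mean()) ** 2)
    return 1 - r @ r / tss


class TestPartition:
    def test_identities_hold_raw_mode(self):
        rng = np.random.default_rng(0)
        Xs = rng.normal(size=(80, 3))
        Xe = rng.normal(size=(80, 2)) + 0.4 * Xs[:, :2]
        y = Xs @ [1, 0.5, 0] + Xe @ [0.8, -0.2] + rng.normal(size=80)
        res = pt.partition(y, Xs, Xe, adjusted=False)
        assert res.pure_spatial + res.shared == pytest.approx(res.r2_spatial, abs=1e-10)
        assert res.pure_environmental + res.shared == pytest.approx(
            res.r2_environmental, abs=1e-10
        )
        assert res.pure_spatial + res.pure_environmental + res.shared == pytest.approx(
            res.r2_full, abs=1e-10
        )
        assert res.residual == pytest.approx(1 - res.r2_full, abs=1e-12)

    def test_identical_tables_are_fully_shared(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 2))
        y = X @ [1.0, -0.5] + rng.normal(size=60)
        res = pt.partition(y, X, X, adjusted=False)
        assert res.pure_spatial == pytest.approx(0.0, abs=1e-10)
        assert res.pure_environmental == pytest.approx(0.0, abs=1e-10)
        assert res.shared == pytest.approx(res.r2_full, abs=1e-10)

    def test_orthogonal_design_has_no_shared_fraction(self):
        rng = np.random.default_rng(2)
        n = 400
        Xs = rng.normal(size=(n, 2))
        Xe = rng.normal(size=(n, 2))
        # orthogonalize env against spatial (and the intercept) exactly
        B = np.column_stack([np.ones(n), Xs])
        Xe = Xe - B @ np.linalg.lstsq(B, Xe, rcond=None)[0]
        y = Xe @ [1.0, 0.5] + rng.normal(size=n)
        res = pt.partition(y, Xs, Xe, adjusted=False)
        assert abs(res.shared) < 0.02
        assert res.pure_environmental == pytest.approx(
            res.r2_environmental, abs=0.02
        )

    def test_pure_noise_fractions_near_zero_adjusted(self):
        rng = np.random.default_rng(3)
        n = 300
        res = pt.partition(
            rng.normal(size=n),
            rng.normal(size=(n, 3)),
            rng.normal(size=(n, 3)),
            adjusted=True,
        )
        for frac in (res.pure_spatial, res.pure_environmental, res.shared):
            assert abs(frac) < 0.05

    def test_negative_adjusted_fractions_not_clipped(self):
        rng = np.random.default_rng(4)
        n = 25  # small n: adjustment overshoots for pure noise
        vals = [
            pt.partition(
                rng.normal(size=n),
                rng.normal(size=(n, 4)),
                rng.normal(size=(n, 4)),
                adjusted=True,
            )
            for _ in range(20)
        ]
        assert any(
            min(v.pure_spatial, v.pure_environmental, v.shared) < 0 for v in vals
        )

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            pt.partition(np.arange(5.0), np.ones((5, 2)), np.ones((5, 3)))


class TestLmg:
    def test_orthogonal_shares_equal_marginal_r2(self):
        n = 64
        X = pd.DataFrame(
            {
                "a": np.tile([1.0, -1.0], n // 2),
                "b": np.tile([1.0, 1.0, -1.0, -1.0], n // 4),
            }
        )
        rng = np.random.default_rng(5)
        y = 1.0 * X["a"].to_numpy() + 0.5 * X["b"].to_numpy() + rng.normal(size=n)
        imp = pt.lmg_importance(y, X)
        for j, c in enumerate(X.columns):
            marg = _r2(X[[c]].to_numpy(), y)
            assert imp.shares[j] == pytest.approx(marg, abs=1e-10)

    def test_p2_closed_form(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(100, 2)), columns=["a", "b"])
        X["b"] += 0.6 * X["a"]
        y = (X["a"] + 0.3 * X["b"] + rng.normal(size=100)).to_numpy()
        imp = pt.lmg_importance(y, X)
        r_a = _r2(X[["a"]].to_numpy(), y)
        r_b = _r2(X[["b"]].to_numpy(), y)
        r_full = _r2(X.to_numpy(), y)
        assert imp.shares[0] == pytest.approx(0.5 * (r_a + r_full - r_b), abs=1e-12)
        assert imp.shares[1] == pytest.approx(0.5 * (r_b + r_full - r_a), abs=1e-12)

    def test_p4_matches_brute_force_ordering_average(self):
        rng = np.random.default_rng(7)
        Z = rng.normal(size=(60, 4))
        Z[:, 1] += 0.5 * Z[:, 0]
        Z[:, 3] -= 0.7 * Z[:, 2]
        X = pd.DataFrame(Z, columns=list("abcd"))
        y = Z @ [1.0, 0.2, -0.5, 0.1] + rng.normal(size=60)
        imp = pt.lmg_importance(y, X)
        brute = np.zeros(4)
        for order in permutations(range(4)):
            r_prev = 0.0
            for pos, j in enumerate(order):
                cols = list(order[: pos + 1])
                r_now = _r2(Z[:, cols], y)
                brute[j] += r_now - r_prev
                r_prev = r_now
        brute /= 24  # 4! orderings
        assert np.allclose(imp.shares, brute, atol=1e-12)

    def test_shares_sum_to_r2_and_relabeling_symmetry(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = (X["a"] - X["c"] + rng.normal(size=50)).to_numpy()
        imp = pt.lmg_importance(y, X)
        assert imp.shares.sum() == pytest.approx(imp.r2, abs=1e-10)
        shuffled = X[["c", "a", "b"]]
        imp2 = pt.lmg_importance(y, shuffled)
        assert imp2.to_series()["a"] == pytest.approx(imp.to_series()["a"], abs=1e-12)

    def test_noise_predictor_perturbs_shares_only_slightly(self):
        rng = np.random.default_rng(9)
        n = 1000
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        y = (X["a"] + 0.5 * X["b"] + rng.normal(size=n)).to_numpy()
        base = pt.lmg_importance(y, X).to_series()
        X2 = X.copy()
        X2["junk"] = rng.normal(size=n)
        with_noise = pt.lmg_importance(y, X2).to_series()
        for c in ("a", "b"):
            assert abs(with_noise[c] - base[c]) < 0.01

    def test_p_limit_suggests_sampling(self):
        X = pd.DataFrame(np.zeros((20, 12)), columns=[f"x{i}" for i in range(12)])
        with pytest.raises(ValueError, match="sampled orderings"):
            pt.lmg_importance(np.zeros(20), X)


class TestDespatialized:
    def test_empty_spatial_basis_reduces_to_plain_lmg(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"])
        y = (X["a"] + rng.normal(size=60)).to_numpy()
        d = pt.despatialized_importance(y, np.empty((60, 0)), X)
        plain = pt.lmg_importance(y, X)
        assert np.allclose(d.shares_residual, plain.shares, atol=1e-10)
        assert d.residual_variance_fraction == pytest.approx(1.0)

    def test_spatially_saturated_response_is_degenerate(self):
        rng = np.random.default_rng(11)
        Xs = rng.normal(size=(40, 2))
        y = Xs @ [1.0, -2.0] + 3.0
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        d = pt.despatialized_importance(y, Xs, X)
        assert d.degenerate
        assert np.allclose(d.shares_total, 0.0)

    def test_share_sum_equals_pure_environmental_fraction(self):
        rng = np.random.default_rng(12)
        Xs = rng.normal(size=(100, 3))
        Xe = pd.DataFrame(rng.normal(size=(100, 2)) + 0.3 * Xs[:, :2],
                          columns=["e1", "e2"])
        y = Xs @ [0.5, 0, 0] + Xe.to_numpy() @ [1.0, -0.4] + rng.normal(size=100)
        d = pt.despatialized_importance(y, Xs, Xe)
        res = pt.partition(y, Xs, Xe.to_numpy(), adjusted=False)
        assert d.shares_total.sum() == pytest.approx(
            res.pure_environmental, abs=1e-10
        )

    def test_truth_ordering_recovered_on_synthetic_river(self):
        """When the color effect truly dominates SRP, the despatialized lmg
        shares put the color ratio first."""
        cfg = syn.demo_config(seed=13, n_transects=30, stations_per_transect=3)
        cfg = dataclasses.replace(
            cfg,
            community=syn.CommunityResponse(
                beta0=0.5, beta_color=1.2, beta_srp=0.4, noise_sd=0.15
            ),
            profile_depth_m=0.5,
        )
        river = syn.simulate_river(cfg)
        t = river.station_table
        y = np.log(t["cyano_euk"].to_numpy())
        X = pd.DataFrame(
            {"blue_red": np.log(t["blue_red"]), "srp": np.log(t["srp"])}
        )
        basis = aem_basis_from_graph(river.graph)
        d = pt.despatialized_importance(y, basis.vectors[:, :3], X)
        s = pd.Series(d.shares_total, index=d.predictors)
        assert s["blue_red"] > s["srp"]


def test_pure_spatial_fraction_grows_with_residual_autocorrelation():
    """Spatially propagated community noise shows up as pure-spatial variance."""
    rng_rhos = [0.0, 0.8]
    means = []
    for rho in rng_rhos:
        fracs = []
        for seed in range(5):
            cfg = syn.demo_config(seed=100 + seed, n_transects=30,
                                  stations_per_transect=3, rho=rho, noise_sd=0.3)
            cfg = dataclasses.replace(cfg, profile_depth_m=0.5)
            river = syn.simulate_river(cfg)
            t = river.station_table
            y = np.log(t["cyano_euk"].to_numpy())
            Xe = np.column_stack([np.log(t["blue_red"]), np.log(t["srp"])])
            basis = aem_basis_from_graph(river.graph)
            res = pt.partition(y, basis.vectors[:, :10], Xe, adjusted=True)
            fracs.append(res.pure_spatial)
        means.append(np.mean(fracs))
    assert means[1] > means[0]
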