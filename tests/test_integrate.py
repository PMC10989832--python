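"""Screens, Mantel, Boruta, piecewise path model, variance partitioning."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from rhizotrace import integrate, synthio
from rhizotrace.errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidConfigError,
)


def frame(arr, prefix="v"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr, index=[f"S{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestSpearmanScreen:
    def test_monotone_transform_passes(self):
        x = frame(np.linspace(1, 9, 10)[:, None], "x")
        y = frame(np.exp(np.linspace(1, 9, 10))[:, None], "y")
        out = integrate.spearman_screen(x, y)
        assert out.edges["r"].iloc[0] == pytest.approx(1.0)
        assert out.edges["passed"].iloc[0]

    def test_sign_convention(self):
        x = frame(np.linspace(1, 9, 10)[:, None], "x")
        y = frame(-np.linspace(1, 9, 10)[:, None], "y")
        assert integrate.spearman_screen(x, y).edges["passed"].iloc[0]
        signed = integrate.spearman_screen(x, y, use_absolute=False)
        assert not signed.edges["passed"].iloc[0]

    def test_constant_variable_flagged_failed(self):
        x = frame(np.ones((10, 1)), "x")
        y = frame(np.arange(10.0)[:, None], "y")
        out = integrate.spearman_screen(x, y)
        assert not out.edges["passed"].iloc[0]
        assert np.isnan(out.edges["r"].iloc[0])

    def test_null_pass_rate_matches_alpha(self):
        hits = total = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = frame(rng.normal(size=(20, 5)), "x")
            y = frame(rng.normal(size=(20, 4)), "y")
            out = integrate.spearman_screen(x, y, r_min=0.0, p_max=0.05)
            hits += int(out.edges["passed"].sum())
            total += len(out.edges)
        assert hits / total == pytest.approx(0.05, abs=0.02)


class TestMantel:
    def test_self_correlation(self):
        rng = np.random.default_rng(0)
        d = squareform(pdist(rng.random((8, 2))))
        r, p = integrate.mantel(d, d, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_exhaustive_matches_brute_force(self):
        rng = np.random.default_rng(1)
        a = squareform(pdist(rng.random((5, 2))))
        b = squareform(pdist(rng.random((5, 2))))
        tri = np.tril_indices(5, k=-1)
        r_obs = stats.spearmanr(a[tri], b[tri]).statistic
        count = 0
        perms = list(itertools.permutations(range(5)))
        for perm in perms:
            bp = b[np.ix_(perm, perm)]
            if stats.spearmanr(a[tri], bp[tri]).statistic >= r_obs - 1e-12:
                count += 1
        r, p = integrate.mantel(a, b, exhaustive=True)
        assert r == pytest.approx(r_obs)
        assert p == pytest.approx(count / len(perms))

    def test_null_p_roughly_uniform(self):
        ps = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            a = squareform(pdist(rng.random((7, 3))))
            b = squareform(pdist(rng.random((7, 3))))
            ps.append(integrate.mantel(a, b, n_perm=199, seed=seed)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_matches_skbio(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(2)
        a = squareform(pdist(rng.random((9, 2))))
        b = squareform(pdist(rng.random((9, 2))))
        r_ours, _ = integrate.mantel(a, b, n_perm=99, seed=0)
        r_ref, _, _ = skbio_dist.mantel(
            skbio_dist.DistanceMatrix(a), skbio_dist.DistanceMatrix(b),
            method="spearman", permutations=0,
        )
        assert r_ours == pytest.approx(r_ref)

    def test_small_matrix_rejected(self):
        with pytest.raises(InsufficientDataError):
            integrate.mantel(np.zeros((3, 3)), np.zeros((3, 3)))


class TestBoruta:
    def test_planted_feature_confirmed(self):
        rng = np.random.default_rng(0)
        X = frame(rng.normal(size=(100, 6)), "f")
        target = X["f0"] + 0.05 * rng.normal(size=100)
        out = integrate.boruta_screen(X, target, n_rounds=25, n_trees=60,
                                      seed=0)
        assert "f0" in out.confirmed()

    def test_noise_features_mostly_rejected(self):
        """Pure-noise features against shadows: the per-dataset luckiest
        feature can linger (its spurious correlation persists across
        rounds), so with tens of candidates the rejected fraction should
        still dominate."""
        rejected = total = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = frame(rng.normal(size=(100, 30)), "f")
            target = rng.normal(size=100)
            out = integrate.boruta_screen(X, target, n_rounds=40, n_trees=50,
                                          importance="impurity", seed=seed)
            rejected += int((out.decisions["decision"] == "rejected").sum())
            total += 30
        assert rejected / total >= 0.9

    def test_zero_rounds_rejected(self):
        X = frame(np.random.default_rng(1).normal(size=(20, 3)))
        with pytest.raises(InvalidConfigError):
            integrate.boruta_screen(X, X["v0"], n_rounds=0)

    def test_single_feature_rejected(self):
        X = frame(np.random.default_rng(2).normal(size=(20, 1)))
        with pytest.raises(InsufficientDataError):
            integrate.boruta_screen(X, X["v0"])


class TestPathModel:
    def test_single_path_recovery(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        y = 0.7 * x + np.sqrt(1 - 0.49) * rng.normal(size=500)
        model = integrate.fit_path_model(
            pd.DataFrame({"x": x, "y": y}), [("x", "y")])
        assert model.coefficient("x", "y") == pytest.approx(0.7, abs=0.1)

    def test_null_paths_stay_small(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = pd.DataFrame({"x": rng.normal(size=500),
                                 "y": rng.normal(size=500)})
            model = integrate.fit_path_model(data, [("x", "y")])
            coef = model.coefficient("x", "y")
            p = model.paths["p"].iloc[0]
            ok += int(abs(coef) < 0.1 and p > 0.05)
        assert ok >= 18  # nominal 5% type-I rate

    def test_noiseless_chain_indirect_effect(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=50)
        data = pd.DataFrame({"a": a, "b": a.copy(), "c": a.copy()})
        model = integrate.fit_path_model(data, [("a", "b"), ("b", "c")])
        eff = model.effects.set_index(["source", "target"])
        assert eff.loc[("a", "c"), "indirect"] == pytest.approx(1.0)
        assert eff.loc[("a", "c"), "total"] == pytest.approx(1.0)

    def test_cyclic_spec_rejected(self):
        data = frame(np.random.default_rng(5).normal(size=(30, 2)))
        with pytest.raises(InvalidConfigError):
            integrate.fit_path_model(data, [("v0", "v1"), ("v1", "v0")])

    def test_collinear_parents_rejected(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=40)
        data = pd.DataFrame({"a": x, "b": x * 2.0,
                             "y": rng.normal(size=40)})
        with pytest.raises(DegenerateInputError):
            integrate.fit_path_model(data, [("a", "y"), ("b", "y")])

    def test_default_dag_recovery(self):
        cfg = synthio.SimulationConfig(seed=5)
        sim = synthio.simulate_integrated(cfg, n_samples=2000)
        dag = list(sim.truth_coefficients)
        model = integrate.fit_path_model(sim.data, dag)
        for (a, b), truth in sim.truth_coefficients.items():
            assert model.coefficient(a, b) == pytest.approx(truth, abs=0.1)


class TestVariancePartition:
    def test_degenerate_partition(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=120)
        vpa = integrate.variance_partition(
            a, a[:, None], rng.normal(size=(120, 1)),
            rng.normal(size=(120, 1)))
        assert vpa.fractions["unique_a"] == pytest.approx(1.0, abs=0.05)
        assert vpa.total_r2 == pytest.approx(1.0, abs=1e-9)

    def test_unadjusted_conservation(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=60)
        vpa = integrate.variance_partition(
            y, rng.normal(size=(60, 2)), rng.normal(size=(60, 2)),
            rng.normal(size=(60, 2)), adjusted=False)
        assert sum(vpa.fractions.values()) + vpa.residual == pytest.approx(
            1.0, abs=1e-9)

    def test_two_block_reduction(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(80, 1))
        b = rng.normal(size=(80, 1))
        y = a[:, 0] + b[:, 0]
        vpa = integrate.variance_partition(y, a, b, None)
        assert set(vpa.fractions) == {"unique_a", "unique_b", "shared_a_b"}
        assert sum(vpa.fractions.values()) == pytest.approx(vpa.total_r2,
                                                            abs=1e-9)

    def test_planted_fractions_match_analytic_truth(self):
        cfg = synthio.SimulationConfig(seed=11)
        sim = synthio.simulate_integrated(cfg, n_samples=200)
        vpa = integrate.variance_partition(
            sim.data["Cd"], sim.data[["metabolite"]], sim.data[["microbe"]],
            sim.data[["soil"]], names=("metabolite", "microbe", "soil"),
        )
        for key, truth in sim.truth_vpa.items():
            if key in vpa.fractions:
                assert vpa.fractions[key] == pytest.approx(truth, abs=0.05), key

    def test_empty_blocks_rejected(self):
        with pytest.raises(InvalidConfigError):
            integrate.variance_partition(np.zeros(10), None, None, None)
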