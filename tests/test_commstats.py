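"""Diversity, ordination and group-difference statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from scipy.special import comb

from rhizotrace import commstats as cs
from rhizotrace.errors import DegenerateInputError, InsufficientDataError

from conftest import random_count_table


def as_table(rows, taxa=None):
    rows = np.atleast_2d(rows)
    taxa = taxa or [f"t{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=[f"S{i}" for i in range(rows.shape[0])],
                        columns=taxa)


class TestAlphaDiversity:
    def test_single_taxon_sample(self):
        out = cs.alpha_diversity(as_table([[10, 0, 0]]))
        assert out.loc["S0", "shannon"] == pytest.approx(0.0)
        assert out.loc["S0", "observed"] == 1

    def test_even_two_taxa_simpson(self):
        out = cs.alpha_diversity(as_table([[5, 5]]))
        assert out.loc["S0", "simpson"] == pytest.approx(0.5)

    def test_chao1_formula(self):
        # S_obs 6, two singletons, one doubleton: 6 + 2^2 / (2*1) = 8
        out = cs.alpha_diversity(as_table([[5, 4, 3, 2, 1, 1]]))
        assert out.loc["S0", "chao1"] == pytest.approx(8.0)

    def test_chao1_no_doubletons_bias_corrected(self):
        # F1 = 2, F2 = 0 -> S_obs + F1(F1-1)/2 = 3 + 1
        out = cs.alpha_diversity(as_table([[5, 1, 1]]))
        assert out.loc["S0", "chao1"] == pytest.approx(4.0)

    def test_matches_skbio(self):
        skbio_div = pytest.importorskip("skbio.diversity.alpha")
        counts = np.array([9, 4, 4, 2, 1, 0, 3])
        out = cs.alpha_diversity(as_table([counts]))
        assert out.loc["S0", "shannon"] == pytest.approx(
            skbio_div.shannon(counts, base=np.e))
        assert out.loc["S0", "simpson"] == pytest.approx(
            skbio_div.simpson(counts))


class TestRarefaction:
    def test_full_depth_equals_observed(self):
        table = as_table([[50, 30, 20, 0]])
        out = cs.rarefaction_curve(table, depths=[100], reps=5, seed=0)
        assert out.loc["S0", 100] == 3

    def test_depth_one(self):
        out = cs.rarefaction_curve(as_table([[10, 10]]), depths=[1],
                                   reps=50, seed=0)
        assert out.loc["S0", 1] == 1.0

    def test_hypergeometric_expectation(self):
        """E[observed taxa] after drawing 10 of [50, 50] without
        replacement has the closed form 2(1 - C(50,10)/C(100,10))."""
        expected = 2 * (1 - comb(50, 10) / comb(100, 10))
        out = cs.rarefaction_curve(as_table([[50, 50]]), depths=[10],
                                   reps=2000, seed=1)
        assert out.loc["S0", 10] == pytest.approx(expected, abs=0.05)

    def test_excess_depth_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="exceeds"):
            out = cs.rarefaction_curve(as_table([[5, 5]]), depths=[11],
                                       reps=3, seed=0)
        assert np.isnan(out.loc["S0", 11])


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        d = cs.bray_curtis(as_table([[3, 1, 0], [3, 1, 0], [0, 0, 7]]))
        assert d.iloc[0, 1] == pytest.approx(0.0)
        assert d.iloc[0, 2] == pytest.approx(1.0)

    def test_hand_value(self):
        d = cs.bray_curtis(as_table([[2, 2], [4, 0]]))
        assert d.iloc[0, 1] == pytest.approx(0.5)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        table = random_count_table(rng, n_samples=5)
        ours = cs.bray_curtis(table).to_numpy()
        ref = squareform(pdist(table.to_numpy(), metric="braycurtis"))
        assert np.allclose(ours, ref, atol=1e-12)


class TestNmds:
    def test_planar_configuration_embeds(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [0.5, 2]])
        delta = squareform(pdist(pts))
        res = cs.nmds(delta, k=2, seed=0)
        assert res.stress < 0.01

    def test_duplicated_points_coincide(self):
        pts = np.array([[0, 0], [0, 0], [3, 0], [0, 4], [2, 2]], dtype=float)
        delta = squareform(pdist(pts))
        res = cs.nmds(delta, k=2, seed=0)
        coords = res.coordinates.to_numpy()
        dup = np.linalg.norm(coords[0] - coords[1])
        scale = np.abs(coords).max()
        assert dup < 0.05 * scale

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        delta = squareform(pdist(rng.random((7, 3))))
        a = cs.nmds(delta, seed=9).coordinates
        b = cs.nmds(delta, seed=9).coordinates
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            cs.nmds(np.zeros((3, 3)), k=2)


def anosim_r_oracle(d, labels):
    """Independent ANOSIM R: mean rank difference over M/2."""
    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))
    ranks = stats.rankdata([d[i, j] for i, j in pairs])
    between = np.array([labels[i] != labels[j] for i, j in pairs])
    m = n * (n - 1) / 2
    return (ranks[between].mean() - ranks[~between].mean()) / (m / 2)


class TestAnosim:
    def test_perfect_separation(self, small_community):
        table, groups = small_community
        d = cs.bray_curtis(table)
        r, p = cs.anosim(d, groups, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_exhaustive_p_matches_brute_force(self):
        rng = np.random.default_rng(4)
        d = squareform(pdist(rng.random((6, 2))))
        labels = np.array(["a", "a", "b", "b", "c", "c"])
        r_obs, p = cs.anosim(d, labels, exhaustive=True)
        assert r_obs == pytest.approx(anosim_r_oracle(d, labels))
        stats_all = [
            anosim_r_oracle(d, labels[list(perm)])
            for perm in itertools.permutations(range(6))
        ]
        p_oracle = np.mean([s >= r_obs - 1e-12 for s in stats_all])
        assert p == pytest.approx(p_oracle)

    def test_null_mean_r_near_zero(self):
        rs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            d = squareform(pdist(rng.random((12, 3))))
            labels = np.array(["a"] * 6 + ["b"] * 6)
            rng.shuffle(labels)
            r, _ = cs.anosim(d, labels, n_perm=49, seed=seed)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05

    def test_matches_skbio(self, small_community):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        table, groups = small_community
        d = cs.bray_curtis(table)
        ref = skbio_dist.anosim(
            skbio_dist.DistanceMatrix(d.to_numpy(), ids=list(d.index)),
            grouping=list(groups), permutations=99,
        )
        r, _ = cs.anosim(d, groups, n_perm=99, seed=0)
        assert r == pytest.approx(ref["test statistic"])

    def test_single_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            cs.anosim(np.zeros((4, 4)), ["a"] * 4)


class TestSimper:
    def test_single_differing_taxon_contributes_everything(self):
        table = as_table([[10, 5], [10, 5], [10, 9], [10, 9]])
        groups = ["a", "a", "b", "b"]
        out = cs.simper(table, groups)
        assert out.iloc[0]["taxon"] == "t1"
        assert out.iloc[0]["contribution_percent"] == pytest.approx(100.0)

    def test_conservation_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            table = random_count_table(rng, n_samples=5, n_taxa=6)
            groups = ["a", "a", "b", "b", "b"]
            out = cs.simper(table, groups)
            bc = cs.bray_curtis(table).to_numpy()
            mean_between = np.mean([bc[i, j] for i in range(2)
                                    for j in range(2, 5)])
            assert out["contribution"].sum() == pytest.approx(
                mean_between, abs=1e-12)

    def test_hand_decomposition(self):
        table = as_table([[4, 0, 4], [4, 2, 2], [0, 4, 4], [2, 4, 2]])
        groups = ["a", "a", "b", "b"]
        out = cs.simper(table, groups).set_index("taxon")
        # brute-force decomposition over the four between-group pairs
        arr = table.to_numpy(dtype=float)
        expected = np.zeros(3)
        for i in (0, 1):
            for j in (2, 3):
                expected += np.abs(arr[i] - arr[j]) / (arr[i] + arr[j]).sum()
        expected /= 4
        for k, taxon in enumerate(table.columns):
            assert out.loc[taxon, "contribution"] == pytest.approx(
                expected[k], abs=1e-12)


class TestWelch:
    def test_identical_groups_give_t_zero(self):
        table = as_table([[5, 5], [6, 4], [5, 5], [6, 4]])
        out = cs.welch_t_table(table, ["a", "a", "b", "b"])
        assert np.allclose(out["t"].abs(), 0.0, atol=1e-12)

    def test_symmetric_input_t_zero(self):
        out = cs.welch_t_table(
            as_table([[1, 9], [2, 8], [3, 7], [1, 9], [2, 8], [3, 7]]),
            ["a"] * 3 + ["b"] * 3, transform="none",
        )
        assert out["t"].abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(0)
        base = rng.integers(90, 110, size=(10, 4))
        base[5:, 0] *= 10  # 10-fold planted shift in taxon 0, group b
        out = cs.welch_t_table(as_table(base), ["a"] * 5 + ["b"] * 5)
        assert out.set_index("taxon").loc["t0", "p"] < 0.01


class TestLefseLite:
    def test_no_structure_usually_empty(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            p = rng.dirichlet(np.full(15, 5.0))
            counts = rng.multinomial(10_000, p, size=16)
            out = cs.lefse_lite(as_table(counts), ["a"] * 8 + ["b"] * 8,
                                seed=seed)
            hits += int(len(out) > 0)
        assert hits <= 5  # empty in >= 90% of null runs

    def test_planted_dominant_taxon_detected(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(50, 150, size=(10, 10))
        counts[5:, 3] += 20_000  # orders-of-magnitude shift toward group b
        out = cs.lefse_lite(as_table(counts), ["a"] * 5 + ["b"] * 5, seed=0)
        assert "t3" in set(out["taxon"])
        assert out.set_index("taxon").loc["t3", "group"] == "b"

    def test_infinite_threshold_empty(self, small_community):
        table, groups = small_community
        out = cs.lefse_lite(table, groups, lda_threshold=np.inf, seed=0)
        assert out.empty


class TestAggregation:
    def test_lineage_prefix_sum(self):
        table = as_table([[1, 2, 3], [4, 5, 6]], taxa=["x", "y", "z"])
        taxonomy = pd.Series({
            "x": "p__A;c__1", "y": "p__A;c__2", "z": "p__B;c__3",
        })
        out = cs.aggregate_taxonomy(table, taxonomy, level=1)
        assert out["p__A"].tolist() == [3, 9]
        assert out["p__B"].tolist() == [3, 6]

    def test_unresolved_bucketed(self):
        table = as_table([[1, 2]], taxa=["x", "y"])
        taxonomy = pd.Series({"x": "p__A"})
        out = cs.aggregate_taxonomy(table, taxonomy, level=1)
        assert "unclassified" in out.columns
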