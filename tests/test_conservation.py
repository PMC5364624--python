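import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.cluster import hierarchy

from limbphylo import conservation

from conftest import toy_profiles


def brute_force_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Independent oracle: average-rank, then plain Pearson."""

    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), dtype=float)
        r[order] = np.arange(1, len(v) + 1)
        # average ties
        for val in np.unique(v):
            mask = v == val
            r[mask] = r[mask].mean()
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


class TestSpearmanMatrix:
    def test_self_correlation_is_one(self):
        p = toy_profiles(10, 3)
        m = conservation.spearman_matrix(p)
        np.testing.assert_allclose(np.diag(m.values), 1.0)

    def test_monotone_transform_invariance(self):
        p = toy_profiles(15, 1, seed=3)
        df = pd.DataFrame({"a": p["p0"], "b": np.exp(p["p0"] * 2 + 1)})
        m = conservation.spearman_matrix(df)
        assert m.loc["a", "b"] == pytest.approx(1.0)

    def test_five_gene_toy_matches_brute_force(self):
        x = np.array([1.0, 5.0, 2.0, 2.0, 9.0])
        y = np.array([3.0, 1.0, 4.0, 8.0, 2.0])
        df = pd.DataFrame({"a": x, "b": y})
        m = conservation.spearman_matrix(df)
        assert m.loc["a", "b"] == pytest.approx(brute_force_spearman(x, y))

    def test_constant_profile_warns_and_is_nan(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            m = conservation.spearman_matrix(df)
        assert np.isnan(m.loc["a", "b"])


class TestMeanPairwiseSpearman:
    def test_two_profiles_equals_single_pair(self):
        p = toy_profiles(20, 2, seed=1)
        c = conservation.mean_pairwise_spearman(p)
        r = conservation.spearman_matrix(p).iloc[0, 1]
        assert c == pytest.approx(r)

    def test_identical_profiles_give_one(self):
        col = np.arange(10, dtype=float)
        p = pd.DataFrame({f"s{i}": col for i in range(4)})
        assert conservation.mean_pairwise_spearman(p) == pytest.approx(1.0)

    def test_three_profile_toy_matches_hand_average(self):
        p = toy_profiles(12, 3, seed=7)
        pairs = [
            stats.spearmanr(p.iloc[:, i], p.iloc[:, j]).statistic
            for i, j in itertools.combinations(range(3), 2)
        ]
        assert conservation.mean_pairwise_spearman(p) == pytest.approx(
            np.mean(pairs)
        )

    @given(scale=st.floats(min_value=0.1, max_value=50.0),
           shift=st.floats(min_value=0.0, max_value=10.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_monotone_per_profile_transform(self, scale, shift):
        p = toy_profiles(15, 3, seed=11)
        q = p.copy()
        q["p1"] = q["p1"] * scale + shift
        q["p2"] = np.log1p(q["p2"])
        assert conservation.mean_pairwise_spearman(
            q
        ) == pytest.approx(conservation.mean_pairwise_spearman(p))


class TestSubsampleConservation:
    def test_intensity_one_zero_ci_width(self):
        p = toy_profiles(30, 4, seed=2)
        res = conservation.subsample_conservation(p, [1.0], n_draws=20, seed=0)
        lo, hi = res.ci[1.0]
        assert lo == pytest.approx(hi)
        assert lo == pytest.approx(res.c)
        np.testing.assert_allclose(res.distributions[1.0], res.c)

    def test_mean_converges_to_full_c(self):
        p = toy_profiles(200, 4, seed=5)
        res = conservation.subsample_conservation(p, [0.8], n_draws=400, seed=1)
        assert np.mean(res.distributions[0.8]) == pytest.approx(res.c, abs=0.02)

    def test_ci_width_non_increasing_in_intensity(self):
        # expectation over seeds
        widths = {0.5: [], 0.7: [], 0.9: []}
        for seed in range(20):
            p = toy_profiles(100, 4, seed=100 + seed)
            res = conservation.subsample_conservation(
                p, [0.5, 0.7, 0.9], n_draws=80, seed=seed
            )
            for f in widths:
                lo, hi = res.ci[f]
                widths[f].append(hi - lo)
        means = {f: np.mean(v) for f, v in widths.items()}
        assert means[0.5] >= means[0.7] >= means[0.9]

    def test_too_small_subset_errors(self):
        p = toy_profiles(10, 3)
        with pytest.raises(ValueError, match="< 3"):
            conservation.subsample_conservation(p, [0.1], n_draws=5, seed=0)

    def test_compare_stages_flags_disjoint_cis(self):
        a = conservation.ConservationResult(c=0.9, k=4, pair_r=pd.DataFrame())
        b = conservation.ConservationResult(c=0.5, k=4, pair_r=pd.DataFrame())
        a.ci[0.7] = (0.85, 0.95)
        b.ci[0.7] = (0.4, 0.6)
        flags = conservation.compare_stages({"ridge": a, "bud": b}, 0.7)
        assert flags[("ridge", "bud")] is True
        b.ci[0.7] = (0.4, 0.9)
        flags = conservation.compare_stages({"ridge": a, "bud": b}, 0.7)
        assert flags[("ridge", "bud")] is False


class TestSignificantClustering:
    @staticmethod
    def planted_profiles(n_genes=60, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        base_a = rng.normal(0, 1, n_genes)
        base_b = rng.normal(0, 1, n_genes)
        cols = {}
        for i in range(3):
            cols[f"a{i}"] = base_a + rng.normal(0, noise, n_genes)
        for i in range(3):
            cols[f"b{i}"] = base_b + rng.normal(0, noise, n_genes)
        return pd.DataFrame(cols)

    def test_true_split_significant(self):
        p = self.planted_profiles()
        sig = conservation.significant_clustering(
            p, n_boot=200, scales=(0.6, 0.8, 1.0, 1.2, 1.4), seed=0
        )
        node = sig.node({"a0", "a1", "a2"})
        assert node.au >= 0.95

    def test_two_profiles_no_pvalues(self):
        p = toy_profiles(10, 2)
        sig = conservation.significant_clustering(p, n_boot=50, seed=0)
        assert sig.nodes == []
        assert len(sig.linkage) == 1

    def test_bp_at_scale_one_matches_exhaustive_enumeration(self):
        # 4-gene toy: enumerate all 4^4 equally likely resamples
        rng = np.random.default_rng(12)
        p = pd.DataFrame(
            rng.normal(size=(4, 4)), columns=["w", "x", "y", "z"]
        )
        values = p.values
        labels = list(p.columns)

        def clusters_of(vals):
            link = hierarchy.average(conservation.spearman_distance(vals))
            return conservation.linkage_clusters(link, labels)

        target_counts: dict[frozenset, int] = {}
        n_tuples = 0
        for idx in itertools.product(range(4), repeat=4):
            n_tuples += 1
            for cl in clusters_of(values[list(idx)]):
                target_counts[cl] = target_counts.get(cl, 0) + 1
        exact_bp = {cl: c / n_tuples for cl, c in target_counts.items()}

        sig = conservation.significant_clustering(
            p, n_boot=4000, scales=(0.75, 1.0, 1.25), seed=3
        )
        observed = {nd.members: nd.bp for nd in sig.nodes}
        for members, bp in observed.items():
            assert bp == pytest.approx(exact_bp.get(members, 0.0), abs=0.05)

    def test_au_matches_bp_for_constant_half(self):
        scales = np.array(conservation.DEFAULT_SCALES)
        au, degenerate = conservation.fit_au(
            scales, np.full(len(scales), 0.5), n_boot=1000
        )
        assert not degenerate
        assert au == pytest.approx(0.5, abs=0.05)

    def test_degenerate_bp_limits(self):
        scales = np.array([0.5, 1.0, 1.5])
        au1, deg1 = conservation.fit_au(scales, np.ones(3), n_boot=100)
        au0, deg0 = conservation.fit_au(scales, np.zeros(3), n_boot=100)
        assert (au1, deg1) == (1.0, True)
        assert (au0, deg0) == (0.0, True)

    def test_newick_export_contains_annotations(self):
        p = self.planted_profiles()
        sig = conservation.significant_clustering(
            p, n_boot=50, scales=(0.8, 1.0, 1.2), seed=0
        )
        nwk = sig.to_newick()
        assert nwk.endswith(";")
        assert "au" in nwk and "bp" in nwk
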