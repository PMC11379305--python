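import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from veldscore.composition import (
    DissimilarityMatrix,
    anosim,
    bray_curtis,
    bray_curtis_pair,
    collinearity_screen,
    simper,
)
from veldscore.survey_io import AbundanceMatrix, Location


def make_matrix(counts, groups=None):
    counts = np.asarray(counts)
    n, s = counts.shape
    locations = []
    if groups is not None:
        locations = [Location(g) for g in groups]
    return AbundanceMatrix(
        site_ids=[f"s{i}" for i in range(n)],
        species_names=[f"sp{j}" for j in range(s)],
        counts=counts,
        locations=locations,
    )


def exact_anosim_p(dm, groups):
    """Brute-force enumeration oracle: rank dissimilarities once, then score
    every distinct assignment of the label multiset to sites."""
    from scipy.stats import rankdata

    groups = np.asarray(groups)
    n = len(groups)
    M = n * (n - 1) // 2
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dm.values[iu])
    rank_matrix = np.zeros((n, n))
    rank_matrix[iu] = ranks
    rank_matrix += rank_matrix.T

    def R(labels):
        labels = np.asarray(labels)
        same = (labels[:, None] == labels[None, :])[iu]
        r = rank_matrix[iu]
        return (r[~same].mean() - r[same].mean()) / (M / 2)

    observed = R(groups)
    uniq, sizes = np.unique(groups, return_counts=True)
    count_ge = 0
    total = 0
    seen = set()
    for perm in itertools.permutations(groups):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if R(perm) >= observed - 1e-12:
            count_ge += 1
    return observed, count_ge / total, total


class TestBrayCurtis:
    def test_identity_is_zero(self):
        assert bray_curtis_pair([3, 1, 2], [3, 1, 2]) == 0.0

    def test_disjoint_is_one(self):
        assert bray_curtis_pair([3, 0, 2], [0, 4, 0]) == 1.0

    def test_hand_computed_pair(self):
        # 1 - 2*(1 + 1)/(3 + 4) = 3/7
        assert bray_curtis_pair([2, 1], [1, 3]) == pytest.approx(3 / 7)

    def test_two_all_zero_sites_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert bray_curtis_pair([0, 0], [0, 0]) == 0.0

    def test_matrix_properties_and_scipy_cross_check(self):
        rng = np.random.default_rng(17)
        counts = rng.integers(0, 20, size=(8, 6))
        counts[counts.sum(axis=1) == 0, 0] = 1
        dm = bray_curtis(make_matrix(counts))
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)
        assert np.all((dm.values >= 0) & (dm.values <= 1))
        for i in range(8):
            for j in range(8):
                if i != j:
                    assert dm.values[i, j] == pytest.approx(
                        scipy_braycurtis(counts[i], counts[j]), abs=1e-12
                    )

    def test_single_site_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(make_matrix([[1, 2]]))


class TestAnosim:
    def _dm(self, values, n):
        return DissimilarityMatrix(
            site_ids=[f"s{i}" for i in range(n)], values=np.asarray(values, float)
        )

    def test_perfect_separation_gives_R_of_one(self):
        # all between-group distances exceed all within-group distances
        v = np.zeros((4, 4))
        within, between = 0.1, 0.9
        for i, j in itertools.combinations(range(4), 2):
            same = (i < 2) == (j < 2)
            v[i, j] = v[j, i] = within if same else between
        res = anosim(self._dm(v, 4), ["a", "a", "b", "b"], method="exact")
        assert res.R == pytest.approx(1.0)

    def test_identical_replicates_give_R_zero(self):
        counts = np.tile([4, 2, 1], (4, 1))
        dm = bray_curtis(make_matrix(counts))
        with pytest.warns(UserWarning, match="identical"):
            res = anosim(dm, ["a", "a", "b", "b"])
        assert res.R == 0.0
        assert res.p_value == 1.0

    def test_singleton_group_rejected(self):
        v = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        with pytest.raises(ValueError, match="fewer than two"):
            anosim(self._dm(v, 3), ["a", "a", "b"])

    def test_exact_enumeration_matches_brute_force(self):
        """Exact mode agrees with an independent full enumeration on a
        6-site, two-groups-of-3 design (20 distinct assignments)."""
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 15, size=(6, 5))
        dm = bray_curtis(make_matrix(counts))
        groups = ["a", "a", "a", "b", "b", "b"]
        res = anosim(dm, groups, method="exact")
        observed, p_oracle, total = exact_anosim_p(dm, groups)
        assert total == 20
        assert res.n_permutations == 20
        assert res.R == pytest.approx(observed, abs=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_montecarlo_approaches_exact(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 12, size=(7, 5))
        counts[counts.sum(axis=1) == 0, 0] = 1
        dm = bray_curtis(make_matrix(counts))
        groups = ["a", "a", "a", "b", "b", "b", "b"]
        exact = anosim(dm, groups, method="exact")
        n_perm = 10_000
        mc = anosim(dm, groups, method="montecarlo", n_permutations=n_perm, seed=5)
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / n_perm)
        assert abs(mc.p_value - exact.p_value) <= 2 * se + 1 / n_perm

    def test_R_statistic_matches_scikit_bio(self):
        """Cross-check the rank-based R against the reference implementation."""
        skbio_anosim = pytest.importorskip("skbio.stats.distance").anosim
        from skbio import DistanceMatrix

        rng = np.random.default_rng(12)
        counts = rng.integers(0, 25, size=(9, 7))
        counts[counts.sum(axis=1) == 0, 0] = 1
        dm = bray_curtis(make_matrix(counts))
        groups = ["a"] * 4 + ["b"] * 5
        ours = anosim(dm, groups, method="montecarlo", n_permutations=99, seed=0)
        theirs = skbio_anosim(
            DistanceMatrix(dm.values, ids=dm.site_ids), grouping=list(groups),
            permutations=99,
        )
        assert ours.R == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        """ANOSIM is rank-based: squaring the dissimilarities (strictly
        monotone on [0,1]) changes neither R nor the exact p."""
        rng = np.random.default_rng(30)
        counts = rng.integers(1, 20, size=(6, 4))
        dm = bray_curtis(make_matrix(counts))
        squared = DissimilarityMatrix(
            site_ids=dm.site_ids, values=dm.values**2
        )
        groups = ["a", "a", "a", "b", "b", "b"]
        r1 = anosim(dm, groups, method="exact")
        r2 = anosim(squared, groups, method="exact")
        assert r1.R == pytest.approx(r2.R, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)


class TestSimper:
    def test_identical_single_site_groups(self):
        counts = np.array([[5, 3, 2], [5, 3, 2]])
        m = make_matrix(counts, groups=["plains", "streams"])
        (res,) = simper(m)
        assert res.overall_mean_dissimilarity == 0.0
        assert np.allclose(res.table["mean_contribution"], 0.0)

    def test_single_species_contributes_everything(self):
        counts = np.array([[5], [3], [8], [1]])
        m = make_matrix(counts, groups=["plains", "plains", "streams", "streams"])
        (res,) = simper(m)
        assert res.table["percent_contribution"].iloc[0] == pytest.approx(100.0)

    def test_contributions_sum_to_mean_between_group_dissimilarity(self):
        """The per-species decomposition reconstructs the mean between-group
        Bray-Curtis value computed independently."""
        rng = np.random.default_rng(44)
        counts = rng.integers(0, 30, size=(6, 4))
        counts[counts.sum(axis=1) == 0, 0] = 1
        groups = ["plains"] * 3 + ["streams"] * 3
        m = make_matrix(counts, groups=groups)
        (res,) = simper(m)
        expected = np.mean(
            [
                bray_curtis_pair(counts[i], counts[j])
                for i in range(3)
                for j in range(3, 6)
            ]
        )
        assert res.overall_mean_dissimilarity / 100 == pytest.approx(
            expected, abs=1e-9
        )
        assert res.table["mean_contribution"].sum() == pytest.approx(
            expected, abs=1e-9
        )
        assert res.table["percent_contribution"].sum() == pytest.approx(
            100.0, abs=1e-9
        )
        assert res.table["cumulative_percent"].iloc[-1] == pytest.approx(
            100.0, abs=1e-9
        )

    def test_pairwise_reconstruction_for_single_site_groups(self):
        """With one site per group the decomposition must equal that pair's
        Bray-Curtis dissimilarity exactly."""
        rng = np.random.default_rng(45)
        x, y = rng.integers(0, 20, size=(2, 8))
        x[0] = max(x[0], 1)
        y[0] = max(y[0], 1)
        m = make_matrix(np.vstack([x, y]), groups=["plains", "uplands"])
        (res,) = simper(m)
        assert res.table["mean_contribution"].sum() == pytest.approx(
            bray_curtis_pair(x, y), abs=1e-12
        )

    def test_three_groups_reported_pairwise(self):
        counts = np.arange(24).reshape(6, 4) + 1
        m = make_matrix(
            counts, groups=["plains", "plains", "streams", "streams",
                            "uplands", "uplands"]
        )
        results = simper(m)
        pairs = {(r.group_a, r.group_b) for r in results}
        assert pairs == {
            ("plains", "streams"),
            ("plains", "uplands"),
            ("streams", "uplands"),
        }

    def test_empty_group_rejected(self):
        m = make_matrix(np.ones((2, 2), dtype=int), groups=["plains", "plains"])
        with pytest.raises(ValueError):
            simper(m)


class TestCollinearityScreen:
    def test_duplicated_variable_dropped(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=30)})
        retained, dropped = collinearity_screen(df, threshold=0.96)
        assert retained == ["a", "c"]
        assert dropped == {"b": "a"}

    def test_below_threshold_pair_kept(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": y})
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.96
        retained, dropped = collinearity_screen(df, threshold=0.96)
        assert retained == ["a", "b"]
        assert dropped == {}

    def test_three_mutually_correlated_keep_exactly_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        df = pd.DataFrame(
            {"a": x, "b": x + 1e-6 * rng.normal(size=50),
             "c": 2 * x + 1e-6 * rng.normal(size=50)}
        )
        retained, dropped = collinearity_screen(df, threshold=0.96)
        assert retained == ["a"]
        assert dropped == {"b": "a", "c": "a"}

    def test_zero_variance_excluded_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            retained, dropped = collinearity_screen(df)
        assert "a" in retained and "b" in retained

    def test_bad_threshold_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError):
            collinearity_screen(df, threshold=1.5)
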