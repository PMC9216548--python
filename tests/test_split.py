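"""PAM clustering, Duda-Hart homogeneity, cluster-number selection, stratification."""

import itertools
import warnings

import numpy as np
import pytest

from conftest import make_matrix
from mplkit.errors import InvalidInputError, InvalidParameterError
from mplkit.split import (
    detect_split_sites,
    duda_hart,
    pam_1d,
    select_k,
    split_table,
    stratify,
)


def pam_cost_oracle(values, k):
    """Minimum total absolute deviation over all C(n, k) medoid subsets."""
    values = np.asarray(values, dtype=float)
    best = np.inf
    for subset in itertools.combinations(range(len(values)), k):
        med = values[list(subset)]
        cost = np.abs(values[:, None] - med[None, :]).min(axis=1).sum()
        best = min(best, cost)
    return best


class TestPam1d:
    def test_two_clear_clusters(self):
        medoids, assignments, cost = pam_1d([0.1, 0.1, 0.9, 0.9], k=2)
        assert medoids == [0.1, 0.9]
        assert assignments.tolist() == [1, 1, 2, 2]
        assert cost == 0.0

    def test_k1_medoid_is_a_median_element(self, rng):
        vals = rng.random(15)
        medoids, _, cost = pam_1d(vals, k=1)
        # 1-D medoid minimizes total absolute deviation: a median element
        oracle = min(np.abs(vals - v).sum() for v in vals)
        assert cost == pytest.approx(oracle)
        assert medoids[0] in vals

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_exhaustive_search(self, seed, k):
        vals = np.random.default_rng(seed).random(9)
        _, _, cost = pam_1d(vals, k)
        assert cost == pytest.approx(pam_cost_oracle(vals, k), abs=1e-12)

    def test_medoids_ascending_and_labels_cover(self, rng):
        vals = rng.random(30)
        medoids, assignments, _ = pam_1d(vals, 3)
        assert medoids == sorted(medoids)
        assert set(assignments) == {1, 2, 3}

    def test_k_exceeding_distinct_rejected(self):
        with pytest.raises(InvalidParameterError):
            pam_1d([0.1, 0.1, 0.9], k=3)

    def test_deterministic_under_input_order(self, rng):
        vals = rng.random(20)
        a = pam_1d(vals, 2)
        b = pam_1d(vals[::-1], 2)
        assert a[0] == b[0]
        assert a[2] == pytest.approx(b[2])


class TestDudaHart:
    def test_clear_bimodal_rejects_homogeneity(self):
        vals = [0.05] * 50 + [0.95] * 50
        homogeneous, ratio, critical = duda_hart(vals)
        assert not homogeneous
        assert ratio == pytest.approx(0.0)
        # direct computation of both sums of squares
        arr = np.asarray(vals)
        ss1 = ((arr - arr.mean()) ** 2).sum()
        assert ss1 > 0 and ratio < critical

    def test_constant_homogeneous_by_convention(self):
        with pytest.warns(UserWarning):
            homogeneous, _, _ = duda_hart([0.4] * 10)
        assert homogeneous

    def test_single_narrow_component_homogeneous(self):
        vals = np.random.default_rng(99).normal(0.5, 0.02, 200)
        homogeneous, ratio, critical = duda_hart(vals)
        assert homogeneous
        assert ratio >= critical

    def test_critical_value_formula(self):
        # p=1, n=100, alpha=0.001: 1 - 2/pi - z*sqrt(2(1 - 8/pi^2)/100)
        from scipy.stats import norm
        _, _, critical = duda_hart(np.random.default_rng(0).random(100))
        z = norm.ppf(0.999)
        expected = 1 - 2 / np.pi - z * np.sqrt(2 * (1 - 8 / np.pi**2) / 100)
        assert critical == pytest.approx(expected, abs=1e-12)

    def test_needs_four_values(self):
        with pytest.raises(InvalidInputError):
            duda_hart([0.1, 0.9, 0.5])


class TestSelectK:
    def test_bimodal_k2_with_exact_assignments(self, rng):
        vals = np.r_[rng.beta(5, 95, 50), rng.beta(95, 5, 50)]
        call = select_k(vals)
        assert call.k == 2
        assert call.assignments[:50].tolist() == [1] * 50
        assert call.assignments[50:].tolist() == [2] * 50
        assert not call.homogeneous

    def test_trimodal_k3(self, rng):
        # genotype-like peaks; equal weights give the test enough power
        vals = np.concatenate([rng.beta(m * 100, (1 - m) * 100, 200)
                               for m in (0.04, 0.45, 0.89)])
        call = select_k(vals)
        assert call.k == 3
        for medoid, mean in zip(call.medoids, (0.04, 0.45, 0.89)):
            assert abs(medoid - mean) <= 0.05

    def test_unimodal_k1(self, rng):
        call = select_k(rng.beta(40, 60, 150))
        assert call.homogeneous and call.k == 1
        assert np.isnan(call.avg_silhouette)
        assert call.assignments.tolist() == [1] * 150

    def test_scale_shift_equivariant(self, rng):
        vals = np.r_[rng.beta(5, 95, 40), rng.beta(95, 5, 40)]
        a = select_k(vals)
        b = select_k(0.5 * vals + 0.1)
        assert a.k == b.k
        assert a.assignments.tolist() == b.assignments.tolist()


class TestDetectSplitSites:
    def test_engineered_split_site_flagged(self, rng):
        vals = rng.beta(45, 55, (12, 60))
        vals[4] = np.r_[rng.beta(5, 95, 30), rng.beta(95, 5, 30)]
        calls = detect_split_sites(make_matrix(vals))
        split = [s for s, c in calls.items() if c.k >= 2]
        assert split == ["cg004"]

    def test_all_unimodal_no_split_sites(self, rng):
        calls = detect_split_sites(make_matrix(rng.beta(80, 20, (8, 50))))
        assert all(c.k == 1 for c in calls.values())

    def test_short_sites_skipped(self, rng):
        vals = np.full((2, 6), np.nan)
        vals[0] = rng.random(6)
        vals[1, :3] = rng.random(3)
        with pytest.warns(UserWarning, match="skipped"):
            calls = detect_split_sites(make_matrix(vals))
        assert list(calls) == ["cg000"]

    def test_table_columns(self, rng):
        calls = detect_split_sites(make_matrix(rng.beta(80, 20, (3, 30))))
        df = split_table(calls)
        assert df.columns.tolist() == ["SITE", "HOMOGENEOUS", "K", "MEDOIDS",
                                       "SILHOUETTE", "DH_RATIO", "DH_CRITICAL"]


class TestStratify:
    def _split_rows(self, rng, pattern):
        """Rows with values 0.05/0.95 following a 0/1 pattern per sample."""
        noise = rng.normal(0, 0.01, (len(pattern), len(pattern[0])))
        base = np.where(np.asarray(pattern, dtype=bool), 0.95, 0.05)
        return np.clip(base + noise, 0, 1)

    def test_single_site_two_groups(self, rng):
        pattern = [[0] * 25 + [1] * 25]
        m = make_matrix(self._split_rows(rng, pattern))
        res = stratify(m, ["cg000"])
        assert res.group_count == 2
        assert sorted(len(g) for _, g in res.groups) == [25, 25]

    def test_independent_sites_attain_product_bound(self, rng):
        # all 8 combinations of three binary sites present across 64 samples
        combos = list(itertools.product([0, 1], repeat=3)) * 8
        pattern = np.array(combos).T
        m = make_matrix(self._split_rows(rng, pattern))
        res = stratify(m, ["cg000", "cg001", "cg002"])
        assert res.group_count == 8

    def test_correlated_sites_collapse_groups(self, rng):
        row = [0] * 25 + [1] * 25
        m = make_matrix(self._split_rows(rng, [row, row]))
        res = stratify(m, ["cg000", "cg001"])
        assert res.group_count == 2  # only 2 of the 4 combinations occur

    def test_group_count_bounded_by_product_of_k(self, corpus, corpus_split_calls):
        split_sites = [s for s, c in corpus_split_calls.items() if c.k >= 2]
        sites = split_sites[:3]
        res = stratify(corpus.matrix, sites, calls=corpus_split_calls)
        bound = int(np.prod([corpus_split_calls[s].k for s in sites]))
        assert res.group_count <= bound
        assert sum(len(g) for _, g in res.groups) == corpus.matrix.n_samples

    def test_groups_ordered_by_size_and_order_is_heatmap_ready(self, rng):
        pattern = [[0] * 35 + [1] * 15]
        m = make_matrix(self._split_rows(rng, pattern))
        res = stratify(m, ["cg000"])
        sizes = [len(g) for _, g in res.groups]
        assert sizes == sorted(sizes, reverse=True)
        ranks = [res.labels[s] for s in res.sample_order]
        assert ranks == sorted(ranks, key=lambda l: -len(dict(res.groups)[l]))

    def test_homogeneous_site_rejected(self, rng):
        m = make_matrix(rng.beta(80, 20, (1, 30)))
        with pytest.raises(InvalidInputError, match="homogeneous"):
            stratify(m, ["cg000"])

    def test_unknown_site_rejected(self, small_matrix):
        with pytest.raises(InvalidInputError):
            stratify(small_matrix, ["cgMissing"])

    def test_hwe_cluster_sizes_near_expected(self, corpus, corpus_split_calls):
        """Sex-split corpus sites: recovered cluster sizes track the sex ratio."""
        truth = corpus.truth
        sex_sites = truth.sites.loc[truth.sites["KIND"] == "split_sex", "SITE"]
        for site in sex_sites:
            call = corpus_split_calls[site]
            assert call.k == 2
            comp = truth.components.loc[site].to_numpy()
            agree = np.mean((call.assignments - 1) == comp)
            assert max(agree, 1 - agree) >= 0.95
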