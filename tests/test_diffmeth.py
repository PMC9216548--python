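"""Mann-Whitney tests, multiple-testing corrections and the differential table."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_matrix
from mplkit.diffmeth import (
    adjust_pvalues,
    bonferroni_threshold,
    differential_table,
    mann_whitney,
)
from mplkit.errors import InvalidInputError, InvalidParameterError


def mw_enumeration_oracle(a, b):
    """Exact two-sided p by enumerating every labeling of the pooled values."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)

    def u_stat(group_a, group_b):
        return sum(1.0 if x > y else 0.5 if x == y else 0.0
                   for x in group_a for y in group_b)

    observed = u_stat(a, b)
    n_extreme = total = 0
    mean_u = n_a * len(b) / 2
    for idx in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(ga, gb)
        total += 1
        if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12:
            n_extreme += 1
    return n_extreme / total


class TestMannWhitney:
    def test_complete_separation_small_n(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2 / 20)  # 2 of C(6,3)=20 labelings as extreme

    def test_identical_groups_p_one(self):
        _, p = mann_whitney([0.2, 0.4, 0.6, 0.8], [0.2, 0.4, 0.6, 0.8])
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_mode_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random(6), rng.random(7)
        _, p = mann_whitney(a, b, mode="exact")
        assert p == pytest.approx(mw_enumeration_oracle(a, b), abs=1e-12)

    def test_exact_and_normal_agree_at_moderate_n(self, rng):
        a, b = rng.random(30), rng.random(30)
        _, p_exact = mann_whitney(a, b, mode="exact")
        _, p_normal = mann_whitney(a, b, mode="normal")
        assert p_normal == pytest.approx(p_exact, abs=0.005)

    def test_auto_switches_on_ties(self, rng):
        # ties force the tie-corrected normal path; exact would mis-state p
        a = [0.1, 0.2, 0.2, 0.3]
        b = [0.2, 0.4, 0.5, 0.6]
        u, p = mann_whitney(a, b, mode="auto")
        _, p_normal = mann_whitney(a, b, mode="normal")
        assert p == p_normal

    def test_label_swap_preserves_p(self, rng):
        a, b = rng.random(12), rng.random(15)
        _, p_ab = mann_whitney(a, b)
        _, p_ba = mann_whitney(b, a)
        assert p_ab == pytest.approx(p_ba, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            mann_whitney([], [1, 2])


class TestCorrections:
    @pytest.mark.parametrize("alpha,n,expected", [
        (0.05, 10, 0.005),
        (0.05, 1, 0.05),
        (0.05, 485512, 0.05 / 485512),
    ])
    def test_bonferroni_threshold(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected)

    def test_genomewide_threshold_below_1e7(self):
        assert bonferroni_threshold(0.05, 485512) == pytest.approx(1.0299e-7, rel=1e-4)
        assert bonferroni_threshold(0.05, 485512) < 1.1e-7

    def test_bonferroni_adjust_hand_formula(self):
        out = adjust_pvalues([0.01, 0.2, 0.9], "bonferroni")
        np.testing.assert_allclose(out, [0.03, 0.6, 1.0])

    def test_bh_step_up_hand_computed(self):
        out = adjust_pvalues([0.01, 0.02, 0.03], "bh")
        np.testing.assert_allclose(out, [0.03, 0.03, 0.03])

    def test_bh_order_preserved(self):
        out = adjust_pvalues([0.03, 0.01, 0.02], "bh")
        np.testing.assert_allclose(out, [0.03, 0.03, 0.03])

    def test_empty_input(self):
        assert len(adjust_pvalues([], "bh")) == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            adjust_pvalues([0.5, 1.2], "bonferroni")

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_adjustment_invariants(self, pvals):
        p = np.asarray(pvals)
        bonf = adjust_pvalues(p, "bonferroni")
        bh = adjust_pvalues(p, "bh")
        assert np.all(bonf <= 1.0)
        assert np.all(bonf >= p - 1e-15)
        assert np.all(bh >= p - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(bh[order]) >= -1e-15)

    def test_bh_matches_hand_step_up_oracle(self, rng):
        p = rng.random(50)
        n = len(p)
        order = np.argsort(p)
        stepped = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
        oracle = np.empty(n)
        oracle[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(adjust_pvalues(p, "bh"), oracle, atol=1e-12)


class TestDifferentialTable:
    def test_engineered_effect_detected_with_inversion(self, rng):
        vals = np.vstack([
            np.r_[rng.normal(0.2, 0.05, 50), rng.normal(0.8, 0.05, 50)].clip(0, 1),
            rng.normal(0.5, 0.05, 100).clip(0, 1),
        ])
        m = make_matrix(vals, samples=[f"S{i}" for i in range(100)])
        ga, gb = m.sample_ids[:50], m.sample_ids[50:]
        df = differential_table(m, ga, gb)
        hit = df[df["SITE"] == "cg000"].iloc[0]
        assert hit["P_BH"] < 1e-7
        assert bool(hit["INVERTED"])
        assert hit["MEDIAN_DIFF"] == pytest.approx(0.6, abs=0.05)

    def test_label_swap_negates_median_diff(self, rng):
        m = make_matrix(rng.random((5, 20)))
        ga, gb = m.sample_ids[:10], m.sample_ids[10:]
        ab = differential_table(m, ga, gb).set_index("SITE")
        ba = differential_table(m, gb, ga).set_index("SITE")
        for site in m.site_ids:
            assert ab.loc[site, "P"] == pytest.approx(ba.loc[site, "P"], abs=1e-12)
            assert ab.loc[site, "MEDIAN_DIFF"] == pytest.approx(
                -ba.loc[site, "MEDIAN_DIFF"], abs=1e-12)

    def test_single_site_table(self, rng):
        m = make_matrix(rng.random((1, 12)))
        df = differential_table(m, m.sample_ids[:6], m.sample_ids[6:])
        assert len(df) == 1

    def test_columns_and_sorting(self, corpus):
        sheet = corpus.sample_sheet
        ga = sheet.loc[sheet["CONDITION"] == "control", "SAMPLE_ID"].tolist()
        gb = sheet.loc[sheet["CONDITION"] == "case", "SAMPLE_ID"].tolist()
        sub = make_matrix(corpus.matrix.values[:80],
                          sites=corpus.matrix.site_ids[:80],
                          samples=corpus.matrix.sample_ids)
        df = differential_table(sub, ga, gb)
        assert df.columns.tolist() == ["SITE", "N_A", "N_B", "U", "P", "P_BONF",
                                       "P_BH", "MEDIAN_DIFF", "INVERTED"]
        assert (df["P_BH"].diff().dropna() >= -1e-15).all()

    def test_effect_size_filter(self, rng):
        m = make_matrix(rng.normal(0.5, 0.01, (10, 40)).clip(0, 1))
        df = differential_table(m, m.sample_ids[:20], m.sample_ids[20:],
                                min_abs_median_diff=0.2)
        assert len(df) == 0
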