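"""Statistics layer: Mann-Whitney, Kruskal-Wallis/Dunn, two-proportion Z,
and implantation-table arithmetic, each against an independent oracle."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy import stats as sps

from glandmorph.stats import (
    ImplantationTable,
    embryos_per_mouse,
    kruskal_wallis_dunn,
    mann_whitney,
    rescue_percentages,
    two_proportion_ztest,
)


def brute_force_mw_p(a, b):
    """Two-sided exact Mann-Whitney p by direct enumeration over subsets."""
    a, b = list(a), list(b)
    pooled = np.asarray(a + b, float)
    n, n1 = len(pooled), len(a)
    ranks = sps.rankdata(pooled)

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0

    center = n1 * (n - n1) / 2.0
    obs = abs(u_of(range(n1)) - center)
    hits = sum(
        1
        for idx in combinations(range(n), n1)
        if abs(u_of(idx) - center) >= obs - 1e-12
    )
    return hits / comb(n, n1)


class TestMannWhitney:
    def test_small_example_exact(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_samples_give_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="exact")
        assert res.p_value == pytest.approx(1.0)
        assert "midranks" in res.method_detail

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=5).tolist()
        b = rng.normal(size=6).tolist()
        res = mann_whitney(a, b, mode="exact")
        assert res.p_value == pytest.approx(brute_force_mw_p(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=30), rng.normal(1.0, size=30)
        res = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided")
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-12)
        assert "normal approximation" in res.method_detail


class TestKruskalWallisDunn:
    def test_hand_computed_rank_sums(self):
        # ranks 1..9 with no ties: H = 12/(N(N+1)) * sum(R^2/n) - 3(N+1) = 7.2
        res = kruskal_wallis_dunn([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2, abs=1e-12)

    def test_group_order_invariance(self):
        g = [[1.0, 5.0, 3.0], [2.0, 8.0], [9.0, 4.0, 7.0, 6.0]]
        r1 = kruskal_wallis_dunn(g, names=["a", "b", "c"])
        r2 = kruskal_wallis_dunn(g[::-1], names=["c", "b", "a"])
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        p1 = r1.pairwise.set_index(["group_a", "group_b"])["p_value"]
        p2 = r2.pairwise.set_index(["group_b", "group_a"])["p_value"]
        for key, val in p1.items():
            assert p2[key] == pytest.approx(val, abs=1e-12)

    def test_degenerate_constant_groups(self):
        res = kruskal_wallis_dunn([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(m, size=7) for m in (0, 0.5, 2.0, -1.0)]
        res = kruskal_wallis_dunn(groups)
        assert (res.pairwise["adjusted_p"] >= res.pairwise["p_value"] - 1e-15).all()

    def test_two_groups_delegate_to_mann_whitney(self):
        res = kruskal_wallis_dunn([[1, 2, 3], [4, 5, 6]])
        assert res.test_name == "mann_whitney"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_dunn([[1.0], [], [2.0]])


class TestTwoProportionZ:
    def test_equal_proportions(self):
        res = two_proportion_ztest(3, 10, 6, 20)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form_example(self):
        # pooled p = 0.15, se = sqrt(0.15*0.85*0.02)
        res = two_proportion_ztest(10, 100, 20, 100)
        assert res.statistic == pytest.approx(-1.98029509, abs=1e-6)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportions_ztest

        z_ref, p_ref = proportions_ztest([17, 9], [40, 55])
        res = two_proportion_ztest(17, 40, 9, 55)
        assert res.statistic == pytest.approx(float(z_ref), abs=1e-10)
        assert res.p_value == pytest.approx(float(p_ref), abs=1e-10)

    def test_antisymmetry(self):
        r1 = two_proportion_ztest(10, 100, 20, 100)
        r2 = two_proportion_ztest(20, 100, 10, 100)
        assert r1.statistic == pytest.approx(-r2.statistic, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_degenerate_pooled_proportion(self):
        res = two_proportion_ztest(0, 10, 0, 12)
        assert res.p_value == 1.0
        assert "degenerate" in res.method_detail

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_ztest(11, 10, 1, 10)


@pytest.fixture
def implantation_table():
    return ImplantationTable(
        {
            "control": dict(
                n_mice_injected=5,
                n_mice_with_embryos=5,
                n_mice_with_IS=5,
                n_embryos_total=36,
                n_embryos_implanted=36,
            ),
            "mutant": dict(
                n_mice_injected=7,
                n_mice_with_embryos=4,
                n_mice_with_IS=0,
                n_embryos_total=17,
                n_embryos_implanted=0,
            ),
            "rescue_intraluminal": dict(
                n_mice_injected=7,
                n_mice_with_embryos=4,
                n_mice_with_IS=3,
                n_embryos_total=12,
                n_embryos_implanted=7,
            ),
            "rescue_ip": dict(
                n_mice_injected=10,
                n_mice_with_embryos=6,
                n_mice_with_IS=4,
                n_embryos_total=27,
                n_embryos_implanted=11,
            ),
        }
    )


class TestImplantationArithmetic:
    def test_embryos_per_mouse(self, implantation_table):
        assert embryos_per_mouse(implantation_table, "control") == pytest.approx(7.2)
        assert embryos_per_mouse(implantation_table, "mutant") == pytest.approx(4.25)

    def test_zero_embryos(self):
        t = ImplantationTable(
            {
                "g": dict(
                    n_mice_injected=1,
                    n_mice_with_embryos=1,
                    n_mice_with_IS=0,
                    n_embryos_total=0,
                    n_embryos_implanted=0,
                )
            }
        )
        assert embryos_per_mouse(t, "g") == 0.0

    def test_rescue_percentages(self, implantation_table):
        il = rescue_percentages(implantation_table, "rescue_intraluminal")
        assert il["mouse_level_display"] == 75
        assert il["embryo_level_display"] == 58
        assert il["embryo_level_pct"] == pytest.approx(100 * 7 / 12)
        ip = rescue_percentages(implantation_table, "rescue_ip")
        assert ip["mouse_level_display"] == 67
        assert ip["embryo_level_display"] == 41

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            ImplantationTable(
                {
                    "g": dict(
                        n_mice_injected=3,
                        n_mice_with_embryos=5,  # more than injected
                        n_mice_with_IS=1,
                        n_embryos_total=4,
                        n_embryos_implanted=1,
                    )
                }
            )
        with pytest.raises(ValueError):
            ImplantationTable(
                {
                    "g": dict(
                        n_mice_injected=5,
                        n_mice_with_embryos=5,
                        n_mice_with_IS=1,
                        n_embryos_total=4,
                        n_embryos_implanted=9,  # more than total
                    )
                }
            )
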