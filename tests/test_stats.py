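import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psitunnel.stats import (
    compare_study,
    comparisons_to_frame,
    exact_u_distribution,
    format_comparisons,
    levene,
    mannwhitney_exact,
    median_iqr,
)


class TestMedianIqr:
    def test_linear_interpolation_example(self):
        q = median_iqr([1, 2, 3, 4, 5])
        assert (q.median, q.q1, q.q3) == (3.0, 2.0, 4.0)

    def test_singleton(self):
        q = median_iqr([7.0])
        assert (q.median, q.q1, q.q3) == (7.0, 7.0, 7.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])

    def test_hinges_agree_with_interpolation_when_n_is_1_mod_4(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=5)
            lin = median_iqr(x, "linear")
            hin = median_iqr(x, "hinges")
            assert (lin.median, lin.q1, lin.q3) == (hin.median, hin.q1, hin.q3)


class TestExactMannWhitney:
    def test_complete_separation_5v5(self):
        r = mannwhitney_exact([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
        assert r.exact
        assert r.U == 0.0
        assert r.p_two_sided == pytest.approx(2 / 252)
        assert round(r.p_two_sided, 3) == 0.008

    def test_identical_samples_p_one(self):
        r = mannwhitney_exact([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_two_sided == 1.0

    @pytest.mark.parametrize(
        "a, u, expected",
        [
            # against b = {5..9}: 5.5 beats one, 10 beats five -> U = 6, etc.
            ([0.0, 1.0, 2.0, 5.5, 10.0], 6, 0.222),
            ([0.0, 1.0, 2.0, 6.5, 10.0], 7, 0.310),
        ],
    )
    def test_5v5_intermediate_u_values(self, a, u, expected):
        b = [5.0, 6.0, 7.0, 8.0, 9.0]
        r = mannwhitney_exact(a, b)
        assert r.exact and r.U == u
        assert round(r.p_two_sided, 3) == expected

    def test_matches_scipy_exact_distribution(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(1)
        for _ in range(100):
            na, nb = rng.integers(2, 11, 2)
            a = rng.normal(size=na)
            b = rng.normal(0.4, 1.3, size=nb)
            assert mannwhitney_exact(a, b).p_two_sided == pytest.approx(
                mannwhitneyu(a, b, method="exact").pvalue, abs=1e-12
            )

    def test_exact_flag_set_for_small_tie_free_samples(self):
        rng = np.random.default_rng(2)
        r = mannwhitney_exact(rng.normal(size=8), rng.normal(size=9))
        assert r.exact
        r_tied = mannwhitney_exact([1.0, 2.0, 2.0], [2.0, 3.0])
        assert not r_tied.exact

    def test_distribution_counts_sum_to_binomial(self):
        from math import comb

        for na, nb in [(5, 5), (3, 8), (10, 10), (20, 20)]:
            counts = exact_u_distribution(na, nb)
            assert counts.sum() == comb(na + nb, na)
            assert np.all(counts[::-1] == counts)  # symmetric null

    def test_minimum_attainable_p_5v5_closed_form(self):
        counts = exact_u_distribution(5, 5)
        assert 2 * counts[0] / counts.sum() == pytest.approx(2 / 252)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.data())
    def test_relabel_symmetry_and_monotone_invariance(self, data):
        pool = data.draw(
            st.lists(
                st.integers(-50, 50).map(float),
                min_size=4,
                max_size=16,
                unique=True,
            )
        )
        split = data.draw(st.integers(2, len(pool) - 2))
        a, b = pool[:split], pool[split:]
        p = mannwhitney_exact(a, b).p_two_sided
        assert mannwhitney_exact(b, a).p_two_sided == pytest.approx(p, abs=1e-12)
        # strictly monotone transform of the pooled data
        fa = [np.exp(v / 25.0) for v in a]
        fb = [np.exp(v / 25.0) for v in b]
        assert mannwhitney_exact(fa, fb).p_two_sided == pytest.approx(p, abs=1e-12)

    def test_exact_close_to_normal_approximation_at_10v10(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = rng.normal(size=10)
            b = rng.normal(0.3, 1, size=10)
            p_exact = mannwhitney_exact(a, b).p_two_sided
            p_norm = mannwhitney_exact(a, b, force_normal=True).p_two_sided
            assert abs(p_exact - p_norm) < 0.02


class TestLevene:
    def test_identical_groups(self):
        W, p = levene([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert W == 0.0 and p == 1.0

    def test_degenerate_perfect_spread_separation_fails(self):
        # |deviations| are {5,5} vs {1,1}: zero within-group variability
        with pytest.raises(ValueError, match="undefined"):
            levene([0.0, 10.0], [4.0, 6.0], center="mean")

    def test_detects_unequal_spread(self):
        """Power against a 3x spread ratio at n=20 per group exceeds 0.8."""
        rng = np.random.default_rng(4)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            a = rng.normal(0, 3.0, 20)
            b = rng.normal(0, 1.0, 20)
            _, p = levene(a, b)
            rejections += p < 0.05
        assert rejections / n_reps > 0.8

    def test_brown_forsythe_variant_runs(self):
        rng = np.random.default_rng(5)
        W, p = levene(rng.normal(size=10), rng.normal(size=10), center="median")
        assert 0 <= p <= 1


class TestCompareStudy:
    @staticmethod
    def _records(rng, n_knees=5):
        import pandas as pd

        rows = []
        for group, scale in (("freehand", 20.0), ("psi", 5.0)):
            for k in range(n_knees):
                for lig in ("LCL", "PT", "MCL", "POL"):
                    rows.append(
                        {
                            "knee_id": f"{group}-{k}",
                            "group": group,
                            "ligament": lig,
                            "angular_deviation_deg": scale * rng.lognormal(0, 0.3),
                            "entry_distance_mm": 5.0 * rng.lognormal(0, 0.4),
                        }
                    )
        return pd.DataFrame(rows)

    def test_row_cardinality(self):
        recs = self._records(np.random.default_rng(6))
        comps = compare_study(recs)
        # 2 outcomes x (pooled + 4 ligaments)
        assert len(comps) == 10
        assert {c.stratum for c in comps} == {"pooled", "LCL", "PT", "MCL", "POL"}
        df = comparisons_to_frame(comps)
        assert len(df) == 10
        assert format_comparisons(comps).count("\n") == 11

    def test_identical_groups_give_p_one(self):
        import pandas as pd

        recs = self._records(np.random.default_rng(7))
        psi = recs[recs.group == "psi"].copy()
        ctrl = psi.copy()
        ctrl["group"] = "freehand"
        comps = compare_study(pd.concat([ctrl, psi]))
        assert all(c.p_mannwhitney == 1.0 for c in comps)

    def test_separated_groups_pooled_angular_significant(self):
        recs = self._records(np.random.default_rng(8))
        comps = {(c.outcome, c.stratum): c for c in compare_study(recs)}
        pooled = comps[("angular", "pooled")]
        assert pooled.exact
        assert pooled.n_control == pooled.n_psi == 20
        assert pooled.p_mannwhitney < 0.001

    def test_missing_stratum_warns_and_omits(self):
        recs = self._records(np.random.default_rng(9))
        recs = recs[~((recs.group == "psi") & (recs.ligament == "POL"))]
        with pytest.warns(UserWarning, match="POL"):
            comps = compare_study(recs)
        assert len(comps) == 8  # POL row dropped for both outcomes
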