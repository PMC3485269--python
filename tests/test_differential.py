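import numpy as np
import pandas as pd
import pytest
from scipy import stats

from srnaherit import differential
from srnaherit.types import ClusterCountMatrix, bio_sample_id


def small_design():
    rows = []
    for gt, n in (("CC", 3), ("LL", 3), ("CL", 4), ("LC", 4)):
        for b in range(1, n + 1):
            rows.append(
                {"library_id": f"{gt}_b{b}_t1", "genotype": gt, "bio_rep": b,
                 "tech_rep": 1, "total_mapped_reads": 1_000_000}
            )
    return pd.DataFrame(rows)


def matrix_from_groups(cc, ll, cl, lc=None):
    cols = {}
    for gt, vals in (("CC", cc), ("LL", ll), ("CL", cl), ("LC", lc)):
        if vals is None:
            continue
        for b, column in enumerate(np.atleast_2d(np.asarray(vals, float)).T, start=1):
            cols[bio_sample_id(gt, b)] = column
    return ClusterCountMatrix(values=pd.DataFrame(cols), stage="filtered")


class TestAnovaDe:
    def test_identical_groups_give_p_one(self):
        m = matrix_from_groups([[10, 10, 10]], [[10, 10, 10]], [[10, 10, 10, 10]])
        de = differential.anova_de(m, small_design(), set_id="III")
        assert de["p"].tolist() == [1.0]
        assert not de["is_de"].any()

    def test_f_statistic_matches_scipy_oracle(self, rng):
        values = rng.normal(50, 10, size=(30, 10))
        m = matrix_from_groups(values[:, :3], values[:, 3:6], values[:, 6:])
        de = differential.anova_de(m, small_design(), set_id="III")
        for i in range(30):
            f, p = stats.f_oneway(values[i, :3], values[i, 3:6], values[i, 6:])
            assert de["F"].iloc[i] == pytest.approx(f)
            assert de["p"].iloc[i] == pytest.approx(p)

    def test_two_group_degenerate_case_equals_pooled_t_squared(self):
        # with two groups the one-way F collapses to the pooled-variance t^2
        cc = np.array([1.0, 2.0, 3.0])
        ll = np.array([4.0, 6.0, 8.0])
        f, p = differential.anova_oneway([cc[None, :], ll[None, :]])
        t, p_t = stats.ttest_ind(cc, ll, equal_var=True)
        assert f[0] == pytest.approx(t**2)
        assert p[0] == pytest.approx(p_t)

    def test_null_fdp_controlled_under_nb_noise(self):
        fdp = differential.null_fdp_calibration(
            seed=0, n_clusters=200, repeats=100, mean=50.0, dispersion=0.1
        )
        assert fdp["mean_fdp"] <= 0.12  # loose smoke bound at this small size
        assert fdp["mean_rejected_fraction"] <= 0.01


class TestBhFdr:
    def test_single_p_is_its_own_q(self):
        assert differential.bh_fdr([0.03]).tolist() == [0.03]

    def test_hand_step_up_computation(self):
        q = differential.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            differential.bh_fdr([0.5, 1.5])

    def test_rejections_match_step_up_oracle_on_random_vectors(self, rng):
        def step_up_rejections(p, alpha):
            # independent oracle: largest k with p_(k) <= alpha*k/m; reject those k
            m = len(p)
            order = np.argsort(p)
            sorted_p = np.asarray(p)[order]
            ks = np.nonzero(sorted_p <= alpha * (np.arange(m) + 1) / m)[0]
            rejected = np.zeros(m, bool)
            if len(ks):
                rejected[order[: ks[-1] + 1]] = True
            return rejected

        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.random(m) ** rng.uniform(0.5, 3)
            alpha = rng.uniform(0.01, 0.2)
            q = differential.bh_fdr(p)
            assert ((q <= alpha) == step_up_rejections(p, alpha)).all()


class TestDaStatistics:
    @pytest.mark.parametrize(
        "hybrid,expected", [(10.0, 1.0), (2.0, -1.0), (6.0, 0.0)]
    )
    def test_da_anchors(self, hybrid, expected):
        a, d, da = differential.compute_da(10.0, 2.0, hybrid)
        assert a == 4.0
        assert da == expected

    def test_da_invariant_to_parent_relabeling(self, rng):
        for _ in range(50):
            cc, ll, h = rng.uniform(1, 100, 3)
            assert differential.compute_da(cc, ll, h)[2] == pytest.approx(
                differential.compute_da(ll, cc, h)[2], nan_ok=True
            )

    def test_equal_parents_flagged_as_nan(self):
        a, d, da = differential.compute_da(5.0, 5.0, 9.0)
        assert a == 0 and np.isnan(da)

    @pytest.mark.parametrize(
        "maternal,paternal,h,expected",
        [(2.0, 10.0, 10.0, 1.0), (10.0, 2.0, 10.0, -1.0), (2.0, 10.0, 6.0, 0.0)],
    )
    def test_parental_da_sign_convention(self, maternal, paternal, h, expected):
        a_prime, da_prime = differential.compute_parental_da(maternal, paternal, h)
        assert da_prime == expected

    def test_parental_da_flips_sign_under_label_swap(self, rng):
        for _ in range(50):
            mat, pat, h = rng.uniform(1, 100, 3)
            if mat == pat:
                continue
            _, d1 = differential.compute_parental_da(mat, pat, h)
            _, d2 = differential.compute_parental_da(pat, mat, h)
            assert d1 == pytest.approx(-d2)


class TestClassifyPattern:
    def test_exact_low_parent_match(self):
        res = differential.classify_pattern(
            [10, 10, 10], [2, 2, 2], [2.0, 2.1, 1.9, 2.0]
        )
        assert res.pattern == "LP"

    def test_exact_midparent_match(self):
        res = differential.classify_pattern(
            [10, 10, 10], [2, 2, 2], [6.0, 6.1, 5.9, 6.0]
        )
        assert res.pattern == "additive"

    @pytest.mark.parametrize("midparent", ["propagated", "one_sample"])
    def test_noiseless_archetypes_recovered_exactly(self, midparent):
        lp, hp = 10.0, 40.0
        jitter = np.array([0.99, 1.0, 1.01])
        hybrid_jitter = np.array([0.99, 1.0, 1.01, 1.0])
        cases = {
            "additive": 25.0, "HP": hp, "LP": lp, "AHP": 60.0, "BLP": 5.0,
            "between_MP_HP": 32.5, "between_MP_LP": 17.5,
        }
        for pattern, mean_h in cases.items():
            res = differential.classify_pattern(
                hp * jitter, lp * jitter, mean_h * hybrid_jitter, midparent=midparent
            )
            assert res.pattern == pattern, f"{pattern} misclassified as {res.pattern}"

    def test_recovery_rate_on_noisy_archetypes(self, rng):
        """Large-effect recovery: fold change 4, CV 10%, n = 3/3/4."""
        lp, hp = 10.0, 40.0
        cases = {
            "additive": 25.0, "HP": hp, "LP": lp, "AHP": 60.0, "BLP": 5.0,
            "between_MP_HP": 32.5, "between_MP_LP": 17.5,
        }
        per_pattern = 200
        hits = {p: 0 for p in cases}
        same_side = {
            "HP": {"HP", "AHP", "between_MP_HP"},
            "AHP": {"HP", "AHP", "between_MP_HP"},
            "between_MP_HP": {"HP", "AHP", "between_MP_HP", "additive"},
            "LP": {"LP", "BLP", "between_MP_LP"},
            "BLP": {"LP", "BLP", "between_MP_LP"},
            "between_MP_LP": {"LP", "BLP", "between_MP_LP", "additive"},
        }
        for pattern, mean_h in cases.items():
            for _ in range(per_pattern):
                res = differential.classify_pattern(
                    rng.normal(hp, 0.1 * hp, 3),
                    rng.normal(lp, 0.1 * lp, 3),
                    rng.normal(mean_h, 0.1 * mean_h, 4),
                )
                if res.pattern == pattern:
                    hits[pattern] += 1
                elif pattern in same_side:
                    # a miscall of a one-sided truth stays on its side of MP
                    assert res.pattern in same_side[pattern], (
                        f"side-crossing confusion {pattern} -> {res.pattern}"
                    )
        # parent-like and beyond-parent patterns recover at the t-test level;
        # the between-MP-HP pattern is power-limited at CV 10% (see methods)
        for pattern in ("additive", "HP", "LP", "AHP", "BLP", "between_MP_LP"):
            assert hits[pattern] / per_pattern >= 0.85, (pattern, hits)

    def test_too_few_replicates_error(self):
        with pytest.raises(ValueError, match="replicates"):
            differential.classify_pattern([10.0], [2, 2, 2], [5, 5, 5, 5])


class TestSummarizePatterns:
    def make_calls(self, counts):
        rows = []
        i = 0
        for pattern, n in counts.items():
            for _ in range(n):
                rows.append({"cluster_id": f"c{i}", "is_de": True, "pattern": pattern})
                i += 1
        return pd.DataFrame(rows).set_index("cluster_id")

    def test_percentages_from_counts(self):
        calls = self.make_calls({"additive": 39, "LP": 52, "AHP": 1, "BLP": 1, "between_MP_LP": 13})
        summary = differential.summarize_patterns(calls)
        assert summary.loc["DE clusters", "count"] == 106
        assert summary.loc["additive", "percent"] == 36.8
        assert summary.loc["non_additive", "count"] == 67
        assert summary.loc["non_additive", "percent"] == 63.2

    def test_zero_de_clusters_give_empty_summary(self):
        calls = pd.DataFrame(columns=["is_de", "pattern"]).rename_axis("cluster_id")
        summary = differential.summarize_patterns(calls)
        assert len(summary) == 0
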