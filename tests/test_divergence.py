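"""Cluster expression divergence and the rank-sum group comparison."""

import itertools
import math

import numpy as np
import pytest

import expevo as ev


def exact_two_sided_p(x, y):
    """Independent oracle: full enumeration of the U null distribution."""
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    pooled = x + y
    u_obs = sum(1 for xi in x for yj in y if xi > yj) + 0.5 * sum(
        1 for xi in x for yj in y if xi == yj
    )
    us = []
    for combo in itertools.combinations(range(n + m), n):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n + m) if i not in combo]
        u = sum(1 for xi in xs for yj in ys if xi > yj) + 0.5 * sum(
            1 for xi in xs for yj in ys if xi == yj
        )
        us.append(u)
    us = np.array(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


class TestMeanEuclid:
    def test_identical_profiles_give_zero(self):
        p = np.full(6, 1 / 6)
        profiles = {f"sp{i}": p for i in range(5)}
        assert ev.pairwise_mean_euclid(profiles) == 0.0

    def test_one_hot_pair_hits_simplex_diameter(self):
        a = np.zeros(6); a[0] = 1.0
        b = np.zeros(6); b[3] = 1.0
        d = ev.pairwise_mean_euclid({"x": a, "y": b})
        assert d == pytest.approx(math.sqrt(2))

    def test_five_species_average_ten_pairs(self):
        rng = np.random.default_rng(17)
        profs = {f"sp{i}": rng.dirichlet(np.ones(6)) for i in range(5)}
        mat = np.vstack(list(profs.values()))
        pairs = [
            np.linalg.norm(mat[i] - mat[j])
            for i, j in itertools.combinations(range(5), 2)
        ]
        assert len(pairs) == 10
        assert ev.pairwise_mean_euclid(profs) == pytest.approx(np.mean(pairs))

    def test_focal_restriction_averages_only_focal_pairs(self):
        rng = np.random.default_rng(18)
        profs = {f"sp{i}": rng.dirichlet(np.ones(6)) for i in range(4)}
        d = ev.pairwise_mean_euclid(profs, focal_species="sp2")
        manual = np.mean(
            [np.linalg.norm(profs["sp2"] - profs[s]) for s in profs if s != "sp2"]
        )
        assert d == pytest.approx(manual)

    def test_off_simplex_profile_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            ev.pairwise_mean_euclid({"a": np.full(6, 0.2), "b": np.full(6, 1 / 6)})

    def test_single_species_rejected(self):
        with pytest.raises(ValueError, match="two species"):
            ev.pairwise_mean_euclid({"a": np.full(6, 1 / 6)})

    def test_species_order_invariance(self):
        rng = np.random.default_rng(19)
        profs = {f"sp{i}": rng.dirichlet(np.ones(6)) for i in range(5)}
        rev = dict(reversed(list(profs.items())))
        assert ev.pairwise_mean_euclid(profs) == pytest.approx(
            ev.pairwise_mean_euclid(rev)
        )


class TestClassify:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            ([1, 1, 0, 0, 0], "functional"),
            ([1, 0, 0, 0, 0], "hypothetical"),
            ([0, 0, 0, 0, 0], "hypothetical"),
            ([1, 1, 1, 1, 1], "functional"),
        ],
    )
    def test_min_two_flagged_members(self, flags, expected):
        assert ev.classify_scog(flags) == expected

    def test_threshold_configurable(self):
        assert ev.classify_scog([1, 1, 0], min_functional=3) == "hypothetical"


class TestMannWhitney:
    def test_spec_example(self):
        res = ev.mann_whitney_u([1, 2], [3, 4])
        assert res.U == 0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 6)

    def test_identical_samples_p_near_one(self):
        res = ev.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_value > 0.9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ev.mann_whitney_u([], [1.0])

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(20)
        for n in (2, 3, 5):
            for m in (2, 4, 6):
                pooled = rng.permutation(np.arange(1.0, n + m + 1))
                x, y = pooled[:n], pooled[n:]
                res = ev.mann_whitney_u(x, y)
                assert res.method == "exact"
                assert res.p_value == pytest.approx(exact_two_sided_p(x, y), abs=1e-12)

    def test_normal_approx_close_to_exact_at_n7(self):
        rng = np.random.default_rng(21)
        x, y = rng.normal(size=7), rng.normal(size=7)
        exact = ev.mann_whitney_u(x, y)
        # force the asymptotic route by adding a tie that does not move U
        from scipy.stats import mannwhitneyu
        approx = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert abs(exact.p_value - approx.pvalue) < 0.02


class TestCompareGroups:
    def _records(self, hyp, fun):
        recs = [
            ev.DivergenceRecord(f"h{i}", v, "hypothetical") for i, v in enumerate(hyp)
        ]
        recs += [
            ev.DivergenceRecord(f"f{i}", v, "functional") for i, v in enumerate(fun)
        ]
        return recs

    def test_single_cluster_per_class(self):
        cmp = ev.compare_groups(self._records([0.5], [0.2]))
        assert cmp.test.p_value == pytest.approx(1.0)
        assert cmp.test.method == "exact"

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            ev.compare_groups(self._records([], [0.1, 0.2]))

    def test_planted_rate_difference_detected(self):
        # hypothetical-class characters evolve 4x faster -> larger divergence
        ds = ev.emit_dataset(
            ev.SimConfig(
                n_genes=400,
                fraction_hypothetical=0.5,
                rate_multiplier=4.0,
                n_planted=0,
                fraction_silent=0.0,
                seed=22,
            )
        )
        res = ev.run_divergence_analysis(ds.matrices, ds.scog_map, ds.flags)
        assert res.pooled.mean_hypothetical > res.pooled.mean_functional
        assert res.pooled.test.p_value < 0.01
        assert set(res.per_species) == set(ds.tree.leaf_names)

    def test_summaries_are_class_means_and_medians(self):
        recs = self._records([0.4, 0.6], [0.1, 0.2, 0.3])
        cmp = ev.compare_groups(recs)
        assert cmp.mean_hypothetical == pytest.approx(0.5)
        assert cmp.median_functional == pytest.approx(0.2)
        assert (cmp.n_hypothetical, cmp.n_functional) == (2, 3)
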