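"""Rank statistics against closed forms, exhaustive permutation oracles and
scipy cross-checks."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from dbprisk.core_data import ValidationError
from dbprisk.nonparam_stats import (
    jonckheere_terpstra,
    jt_count,
    kruskal_wallis_h,
    mann_whitney_u,
    mann_whitney_z,
    spearman_matrix,
)

# ---------------------------------------------------------------------------
# Independent enumeration oracles (brute-force pair counting over all
# equally-likely assignments of the pooled values to groups)
# ---------------------------------------------------------------------------


def pair_count_u(x, y):
    """U for x by direct pair counting (wins + half-ties)."""
    return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)


def pair_count_jt(groups):
    return sum(
        (bj > ai) + 0.5 * (bj == ai)
        for a, b in itertools.combinations(groups, 2)
        for ai in a
        for bj in b
    )


def enumerate_u_distribution(pooled, n1):
    """All C(n, n1) group assignments and their U values."""
    pooled = list(pooled)
    idx = range(len(pooled))
    for chosen in itertools.combinations(idx, n1):
        x = [pooled[i] for i in chosen]
        y = [pooled[i] for i in idx if i not in chosen]
        yield pair_count_u(x, y)


def enumerate_jt_distribution(pooled, sizes):
    """All multinomial assignments of the pooled values to ordered groups."""
    pooled = list(pooled)

    def rec(remaining, sizes_left):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        for chosen in itertools.combinations(range(len(remaining)), k):
            group = [remaining[i] for i in chosen]
            rest = [remaining[i] for i in range(len(remaining)) if i not in chosen]
            for tail in rec(rest, sizes_left[1:]):
                yield [group] + tail

    for assignment in rec(pooled, list(sizes)):
        yield pair_count_jt(assignment)


SMALL_CONFIGS = [
    ([1, 2, 3], [4, 5, 6]),
    ([1, 1, 2], [2, 3]),
    ([5, 1, 4, 2], [3, 3, 6]),
    ([1.5, 2.5], [0.5, 2.5, 3.5, 2.5]),
    ([7], [1, 2, 3, 4, 5, 6, 7]),
    ([2, 2, 2], [2, 2]),
]


class TestMannWhitney:
    def test_symmetric_samples_give_zero(self):
        assert mann_whitney_z([1, 2, 3], [1, 2, 3]).statistic == 0.0

    def test_fully_separated_samples(self):
        res = mann_whitney_z([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-4.5 / math.sqrt(5.25), rel=1e-12)
        assert res.statistic == pytest.approx(-1.964, abs=5e-4)
        assert res.p == pytest.approx(2 * sps.norm.sf(4.5 / math.sqrt(5.25)), rel=1e-12)

    def test_sign_convention_first_sample_larger_positive(self):
        assert mann_whitney_z([4, 5, 6], [1, 2, 3]).statistic > 0

    def test_constant_equal_samples_degenerate(self):
        res = mann_whitney_z([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.statistic == 0.0 and res.p == 1.0

    @pytest.mark.parametrize("x, y", SMALL_CONFIGS)
    def test_u_matches_enumeration_oracle(self, x, y):
        assert mann_whitney_u(x, y) == pytest.approx(pair_count_u(x, y), abs=1e-12)

    @pytest.mark.parametrize("x, y", SMALL_CONFIGS)
    def test_normal_p_tracks_exact_p(self, x, y):
        # At n <= 8 the normal approximation is coarse; require order-of-
        # magnitude agreement with the exact enumeration p, not precision.
        u_obs = mann_whitney_u(x, y)
        dist = np.array(list(enumerate_u_distribution(x + y, len(x))))
        mu = len(x) * len(y) / 2.0
        exact_p = np.mean(np.abs(dist - mu) >= abs(u_obs - mu) - 1e-12)
        res = mann_whitney_z(x, y)
        assert exact_p / 3.0 <= res.p <= min(1.0, exact_p * 3.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_z([], [1.0])

    @given(
        x=st.lists(st.integers(0, 5), min_size=2, max_size=12),
        y=st.lists(st.integers(0, 5), min_size=2, max_size=12),
    )
    def test_invariant_under_monotone_transform(self, x, y):
        base = mann_whitney_z(x, y).statistic
        for f in (lambda v: 3.0 * v + 1.0, math.exp, lambda v: v**3 + v):
            fx, fy = [f(v) for v in x], [f(v) for v in y]
            assert mann_whitney_z(fx, fy).statistic == pytest.approx(base, rel=1e-12, abs=1e-12)


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        res = kruskal_wallis_h([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_constant_degenerate(self):
        res = kruskal_wallis_h([[5, 5], [5, 5, 5]])
        assert res.statistic == 0.0 and res.p == 1.0

    @pytest.mark.parametrize("x, y", SMALL_CONFIGS)
    def test_two_groups_equal_squared_mw_z(self, x, y):
        z = mann_whitney_z(x, y).statistic
        h = kruskal_wallis_h([x, y]).statistic
        assert h == pytest.approx(z**2, abs=1e-10)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(3)
        groups = [rng.integers(0, 8, size=n).astype(float) for n in (9, 14, 11)]
        ours = kruskal_wallis_h(groups)
        ref = sps.kruskal(*groups)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_chi_square_p_close_to_enumeration(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        res = kruskal_wallis_h(groups)
        h_obs = res.statistic
        hs = []
        for jt_groups in _all_assignments([1, 2, 3, 4, 5, 6], (2, 2, 2)):
            hs.append(kruskal_wallis_h(jt_groups).statistic)
        exact_p = np.mean(np.array(hs) >= h_obs - 1e-12)
        assert abs(res.p - exact_p) < 0.15

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis_h([[1, 2, 3]])


def _all_assignments(pooled, sizes):
    def rec(remaining, sizes_left):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        for chosen in itertools.combinations(range(len(remaining)), k):
            group = [remaining[i] for i in chosen]
            rest = [remaining[i] for i in range(len(remaining)) if i not in chosen]
            for tail in rec(rest, sizes_left[1:]):
                yield [group] + tail

    yield from rec(list(pooled), list(sizes))


class TestJonckheereTerpstra:
    def test_textbook_example(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        assert jt_count(groups) == 12.0
        res = jonckheere_terpstra(groups)
        assert res.statistic == pytest.approx(6.0 / math.sqrt(456.0 / 72.0), rel=1e-12)
        assert res.statistic == pytest.approx(2.384, abs=5e-4)

    def test_identical_constant_groups(self):
        res = jonckheere_terpstra([[3, 3], [3, 3], [3]])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_reversing_order_negates_z(self):
        groups = [[1, 5, 2], [3, 3], [4, 6, 6]]
        forward = jonckheere_terpstra(groups).statistic
        backward = jonckheere_terpstra(groups[::-1]).statistic
        assert backward == pytest.approx(-forward, rel=1e-12)

    @pytest.mark.parametrize(
        "groups",
        [
            ([1, 2], [3, 4], [5, 6]),
            ([1, 1], [1, 2], [2, 3]),
            ([4, 2, 7], [1, 1], [5, 9, 9]),
            ([2], [1, 3], [2, 2, 4]),
        ],
    )
    def test_count_matches_enumeration_oracle(self, groups):
        groups = [list(g) for g in groups]
        assert jt_count(groups) == pytest.approx(pair_count_jt(groups), abs=1e-12)
        pooled = [v for g in groups for v in g]
        dist = np.array(list(enumerate_jt_distribution(pooled, [len(g) for g in groups])))
        mu = dist.mean()
        # the closed-form null mean matches the enumeration mean
        n = len(pooled)
        sizes = np.array([len(g) for g in groups])
        assert mu == pytest.approx((n**2 - (sizes**2).sum()) / 4.0, rel=1e-12)
        # and the tie-corrected variance matches the enumeration variance
        res = jonckheere_terpstra(groups)
        if res.statistic != 0.0:
            var_impl = ((jt_count(groups) - mu) / res.statistic) ** 2
            assert var_impl == pytest.approx(dist.var(), rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            jonckheere_terpstra([[1, 2, 3]])

    @given(
        data=st.lists(
            st.lists(st.integers(0, 4), min_size=2, max_size=8), min_size=2, max_size=4
        )
    )
    def test_invariant_under_monotone_transform(self, data):
        base = jonckheere_terpstra(data).statistic
        transformed = [[math.exp(v) for v in g] for g in data]
        assert jonckheere_terpstra(transformed).statistic == pytest.approx(
            base, rel=1e-12, abs=1e-12
        )


class TestSpearman:
    def test_perfect_inverse(self):
        m = spearman_matrix({"x": [1, 2, 3], "y": [3, 2, 1]})
        assert m.r.loc["x", "y"] == pytest.approx(-1.0)

    def test_identical_columns(self):
        m = spearman_matrix({"x": [1, 5, 2, 4], "y": [1, 5, 2, 4]})
        assert m.r.loc["x", "y"] == pytest.approx(1.0)
        assert m.p.loc["x", "y"] == 0.0

    def test_matches_scipy_rank_then_correlate(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        m = spearman_matrix({"x": x, "y": y})
        ref_r, ref_p = sps.spearmanr(x, y)
        assert m.r.loc["x", "y"] == pytest.approx(ref_r, abs=1e-12)
        assert m.p.loc["x", "y"] == pytest.approx(ref_p, rel=1e-9)

    def test_matrix_shape_invariants(self):
        rng = np.random.default_rng(4)
        data = {k: rng.normal(size=25) for k in "abcd"}
        data["b"] = np.round(data["b"])  # introduce ties
        m = spearman_matrix(data)
        r = m.r.to_numpy()
        assert np.allclose(r, r.T, equal_nan=True)
        assert np.allclose(np.diag(r), 1.0)
        off = r[~np.eye(4, dtype=bool)]
        assert (np.abs(off) <= 1.0 + 1e-12).all()

    def test_constant_column_reported_na(self):
        m = spearman_matrix({"x": [1, 2, 3, 4], "c": [7, 7, 7, 7]})
        assert np.isnan(m.r.loc["x", "c"])
        assert m.tier.loc["x", "c"] == "na"

    def test_pairwise_complete_missing_values(self):
        x = [1.0, 2.0, 3.0, 4.0, np.nan]
        y = [2.0, 1.0, 4.0, 3.0, 9.0]
        m = spearman_matrix({"x": x, "y": y})
        ref_r, _ = sps.spearmanr([1, 2, 3, 4], [2, 1, 4, 3])
        assert m.n.loc["x", "y"] == 4
        assert m.r.loc["x", "y"] == pytest.approx(ref_r, abs=1e-12)

    def test_significance_tiers(self):
        rng = np.random.default_rng(20)
        x = np.arange(30.0)
        strong = x + rng.normal(scale=1.0, size=30)
        noise = rng.normal(size=30)
        m = spearman_matrix({"x": x, "strong": strong, "noise": noise})
        assert m.tier.loc["x", "strong"] == "**"
        assert m.tier.loc["x", "noise"] == ""
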