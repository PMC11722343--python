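"""Paired signed-rank, gated unpaired comparison and Kruskal-Wallis."""

import itertools

import numpy as np
import pytest
import scipy.stats

import tmequant as tq
from tmequant.errors import ValidationError
from tmequant.stats import significance_stars


def exact_signed_rank_p(d):
    """Exhaustive 2^n sign-permutation oracle for the two-sided p-value."""
    r = scipy.stats.rankdata(np.abs(d))
    w = r[d > 0].sum()
    dist = np.array(
        [sum(ri for ri, s in zip(r, signs) if s)
         for signs in itertools.product([0, 1], repeat=len(d))]
    )
    return min(2 * min((dist <= w).mean(), (dist >= w).mean()), 1.0)


def test_signed_rank_matches_enumeration_n6():
    rng = np.random.default_rng(2)
    for _ in range(10):
        d = rng.normal(0.5, 1.0, 6)
        res = tq.paired_signed_rank(np.zeros(6), d)
        assert res.p_value == pytest.approx(exact_signed_rank_p(d))


def test_signed_rank_constant_shift_n10():
    """y = x + c: the most extreme table, two-sided p = 2/2^10."""
    x = np.arange(10, dtype=float)
    res = tq.paired_signed_rank(x, x + 3.0)
    assert res.p_value == pytest.approx(2 / 2**10)
    assert res.stars == "**"


def test_signed_rank_all_zero_differences():
    res = tq.paired_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.p_value == 1.0


def test_signed_rank_zero_differences_dropped():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    y = np.array([1.0, 2.5, 3.5, 4.5, 5.5, 6.5])  # first pair ties
    res = tq.paired_signed_rank(x, y)
    assert res.gate["n_nonzero"] == 5
    assert res.p_value == pytest.approx(exact_signed_rank_p((y - x)[1:]))


def test_signed_rank_requires_three_nonzero_pairs():
    with pytest.raises(ValidationError):
        tq.paired_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.5])
    with pytest.raises(ValidationError):
        tq.paired_signed_rank([1.0, 2.0], [3.0, 4.0, 5.0])


def test_signed_rank_large_n_uses_normal_approximation():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 40)
    y = x + rng.normal(0.5, 1, 40)
    res = tq.paired_signed_rank(x, y)
    assert res.gate["method"] == "approx"
    assert 0 <= res.p_value <= 1


def test_signed_rank_invariant_to_monotone_transform():
    rng = np.random.default_rng(4)
    x = rng.uniform(1, 2, 8)
    y = x * rng.uniform(1.05, 1.6, 8)
    p1 = tq.paired_signed_rank(x, y).p_value
    # log preserves the order AND the sign/rank structure of differences only
    # when differences keep relative order; use a rank-preserving map of the
    # raw differences instead
    d = y - x
    p2 = tq.paired_signed_rank(np.zeros_like(d), np.sign(d) * scipy.stats.rankdata(np.abs(d))).p_value
    assert p1 == pytest.approx(p2)


def test_gate_selects_mannwhitney_on_unequal_variance():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, 30)
    y = rng.normal(0, 5, 30)
    res = tq.gated_unpaired_compare(x, y)
    assert res.gate["gate_p"] < 0.05
    assert res.gate["branch"] == "mannwhitney"
    assert res.p_value == res.gate["mannwhitney_p"]


def test_gate_selects_ttest_on_equal_variance():
    rng = np.random.default_rng(6)
    x = rng.normal(0, 1, 30)
    y = rng.normal(0.3, 1, 30)
    res = tq.gated_unpaired_compare(x, y)
    assert res.gate["branch"] == "ttest"
    assert res.p_value == res.gate["ttest_p"]
    assert res.gate["mannwhitney_p"] is not None  # both branches retained


def test_gate_identical_samples_p_one():
    x = np.full(10, 2.0)
    res = tq.gated_unpaired_compare(x, x.copy())
    assert res.p_value == 1.0
    assert res.gate["branch"] == "ttest"


def test_mannwhitney_branch_matches_rank_permutation_oracle():
    rng = np.random.default_rng(9)
    x, y = rng.normal(0, 1, 4), rng.normal(1.5, 1, 4)
    res = tq.gated_unpaired_compare(x, y)
    pooled = np.concatenate([x, y])
    r = scipy.stats.rankdata(pooled)
    obs_u = r[:4].sum() - 4 * 5 / 2
    dist = np.array(
        [r[list(c)].sum() - 4 * 5 / 2 for c in itertools.combinations(range(8), 4)]
    )
    p_oracle = min(2 * min((dist <= obs_u).mean(), (dist >= obs_u).mean()), 1.0)
    assert res.gate["mannwhitney_p"] == pytest.approx(p_oracle)


def test_shapiro_gate_available():
    rng = np.random.default_rng(12)
    x = rng.exponential(1, 40)  # clearly non-normal
    y = rng.exponential(1, 40)
    res = tq.gated_unpaired_compare(x, y, gate="shapiro")
    assert res.gate["branch"] == "mannwhitney"


def test_kruskal_identical_groups_h_zero():
    res = tq.multigroup_compare([2.0, 2.0], [2.0, 2.0], [2.0, 2.0])
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_kruskal_matches_hand_formula():
    groups = [[1.0, 3.0], [2.0, 5.0], [4.0, 6.0]]
    res = tq.multigroup_compare(*groups)
    pooled = np.concatenate(groups)
    ranks = scipy.stats.rankdata(pooled)
    n = len(pooled)
    idx = 0
    h = 0.0
    for g in groups:
        rsum = ranks[idx: idx + len(g)].sum()
        h += rsum**2 / len(g)
        idx += len(g)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    assert res.statistic == pytest.approx(h)


def test_kruskal_two_group_decision_agrees_with_mannwhitney():
    rng = np.random.default_rng(15)
    for shift in (0.0, 3.0):
        x, y = rng.normal(0, 1, 20), rng.normal(shift, 1, 20)
        kw = tq.multigroup_compare(x, y)
        mw = scipy.stats.mannwhitneyu(x, y, alternative="two-sided")
        assert (kw.p_value < 0.05) == (mw.pvalue < 0.05)


@pytest.mark.parametrize(
    "p, stars",
    [(0.04, "*"), (0.004, "**"), (4e-4, "***"), (4e-5, "****"), (0.2, "ns")],
)
def test_star_convention(p, stars):
    assert significance_stars(p) == stars


def test_benjamini_hochberg_monotone():
    p = [0.001, 0.01, 0.04, 0.2, 0.9]
    adj = tq.benjamini_hochberg(p)
    assert (np.diff(adj) >= 0).all()
    assert (adj >= p).all()


def test_type_one_error_calibrated_under_null():
    """Nominal alpha=0.05 holds for n=12 pairs under a Gaussian null."""
    rng = np.random.default_rng(100)
    n_reps = 2000
    rejections = 0
    for _ in range(n_reps):
        d = rng.normal(0, 1, 12)
        if tq.paired_signed_rank(np.zeros(12), d).p_value < 0.05:
            rejections += 1
    rate = rejections / n_reps
    assert 0.03 <= rate <= 0.07
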