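"""Fold-change ranking, extreme sets, percentile groups, expression statistics."""

import math

import numpy as np
import pytest
from scipy import stats

from methylome.differential import (
    DifferentialGeneResult,
    concordance_sample,
    differential_table,
    expression_ttest,
    fold_change,
    linear_correlation,
    noncpg_percentile_groups,
    rank_correlation,
    select_extremes,
)
from methylome.features import RegionMethylationSummary

from conftest import make_sites


def _summary(gid, level, n=10, defined=True):
    return RegionMethylationSummary(gid, "GB", "CpG", n, level, 0.5, defined)


# ---------------------------------------------------------------------------
# fold change + filtering
# ---------------------------------------------------------------------------

def test_fold_change_values():
    assert fold_change(0.3, 0.3) == 0.0
    assert fold_change(0.4, 0.1, eps=0.01) == pytest.approx(math.log2(0.41 / 0.11))
    assert fold_change(0.4, 0.1, eps=0.01) == pytest.approx(1.898, abs=5e-4)
    assert fold_change(0.1, 0.4) == pytest.approx(-fold_change(0.4, 0.1))  # swap negates


def test_differential_table_filters():
    a = {"g1": _summary("g1", 0.04), "g2": _summary("g2", 0.5),
         "g3": _summary("g3", 0.5, defined=False), "g4": _summary("g4", 0.06)}
    b = {"g1": _summary("g1", 0.06), "g2": _summary("g2", 0.1),
         "g3": _summary("g3", 0.5), "g4": _summary("g4", 0.05)}
    res = {r.gene_id: r for r in differential_table(a, b, "GB")}
    assert res["g1"].category == "filtered"  # sum 0.10 is not > 0.10
    assert res["g3"].category == "filtered"  # undefined in one tissue
    assert res["g2"].category == "not_extreme"
    assert res["g4"].category == "not_extreme"  # sum 0.11 passes


def test_select_extremes_sizes_and_disjoint():
    res = [DifferentialGeneResult(f"g{i:03d}", "GB", 0.5, 0.5, fc, "not_extreme")
           for i, fc in enumerate(np.linspace(-2, 2, 400))]
    hyper, hypo = select_extremes(res, 0.025)
    assert len(hyper) == len(hypo) == 10  # floor(0.025 * 400)
    assert not set(hyper) & set(hypo)
    assert min(r.fold_change for r in res if r.gene_id in hyper) > \
        max(r.fold_change for r in res if r.gene_id in hypo)


def test_select_extremes_all_ties_deterministic():
    res = [DifferentialGeneResult(f"g{i}", "GB", 0.5, 0.5, 0.0, "not_extreme")
           for i in range(40)]
    h1 = select_extremes(res, 0.1)
    res2 = [DifferentialGeneResult(f"g{i}", "GB", 0.5, 0.5, 0.0, "not_extreme")
            for i in range(40)]
    h2 = select_extremes(res2, 0.1)
    assert h1 == h2
    assert not set(h1[0]) & set(h1[1])


def test_select_extremes_empty():
    assert select_extremes([], 0.025) == ([], [])


# ---------------------------------------------------------------------------
# percentile groups
# ---------------------------------------------------------------------------

def test_percentile_groups_even_split():
    summaries = {f"g{i:03d}": _summary(f"g{i:03d}", i / 100) for i in range(80)}
    groups = noncpg_percentile_groups(summaries, "GB", 40)
    sizes = np.bincount([g.group for g in groups])[1:]
    assert sizes.tolist() == [2] * 40
    lowest = min(summaries.values(), key=lambda s: s.mean_level).gene_id
    assert next(g.group for g in groups if g.gene_id == lowest) == 1


def test_percentile_groups_remainder_to_highest():
    summaries = {f"g{i:03d}": _summary(f"g{i:03d}", i / 100) for i in range(81)}
    groups = noncpg_percentile_groups(summaries, "GB", 40)
    sizes = np.bincount([g.group for g in groups])[1:]
    assert sizes.tolist() == [2] * 39 + [3]
    assert len({g.gene_id for g in groups}) == 81  # partition


def test_percentile_groups_too_few_genes():
    with pytest.raises(ValueError):
        noncpg_percentile_groups({f"g{i}": _summary(f"g{i}", 0.1) for i in range(39)}, "GB")


# ---------------------------------------------------------------------------
# expression statistics
# ---------------------------------------------------------------------------

def test_ttest_textbook_example():
    t, p = expression_ttest([1, 2, 3], [4, 5, 6])
    # pooled-variance formula by hand: sp2 = 1, t = -3 / sqrt(2/3)
    assert t == pytest.approx(-3 / math.sqrt(2 / 3))
    assert t == pytest.approx(-3.674, abs=5e-4)
    assert p == pytest.approx(2 * stats.t.cdf(t, df=4))
    assert p == pytest.approx(0.0213, abs=5e-4)


def test_ttest_degenerate_and_invariance(rng):
    assert expression_ttest([2, 2], [2, 2]) == (0.0, 1.0)
    t, p = expression_ttest([1, 1], [2, 2])
    assert math.isinf(t) and p == 0.0
    a, b = rng.random(10), rng.random(12)
    t1, _ = expression_ttest(a, b)
    t2, _ = expression_ttest(5 * a, 5 * b)
    assert t1 == pytest.approx(t2)  # scale invariance


def test_correlations():
    x = [1, 2, 3, 4, 5]
    assert rank_correlation(x, [2, 4, 9, 16, 30])[0] == pytest.approx(1.0)
    assert rank_correlation(x, [30, 16, 9, 4, 2])[0] == pytest.approx(-1.0)
    assert rank_correlation([1, 2, 3, 4], [2, 1, 4, 3])[0] == pytest.approx(0.6)
    r, _ = linear_correlation(x, [2.0 * v + 1 for v in x])
    assert r == pytest.approx(1.0)
    assert math.isnan(rank_correlation([1, 1, 1], [1, 2, 3])[0])  # zero variance


# ---------------------------------------------------------------------------
# cross-platform concordance
# ---------------------------------------------------------------------------

def _platform(rng, n=3000, depth=40, noise=False, truth=None):
    pos = np.arange(n) * 7
    if truth is None:
        truth = rng.random(n)
    recs = []
    for p, lv in zip(pos, truth):
        m = rng.binomial(depth, lv) if noise else int(round(lv * depth))
        recs.append(("chr1", int(p), "+", "CpG", "CpG", m, depth))
    return make_sites(recs), truth


def test_concordance_identical_platforms(rng):
    a, _ = _platform(rng)
    r, n = concordance_sample(a, a, n=2000, seed=5)
    assert r == pytest.approx(1.0)
    assert n == 2000


def test_concordance_deterministic_in_seed(rng):
    a, truth = _platform(rng)
    b, _ = _platform(rng, noise=True, truth=truth)  # resampled reads, same truth
    r1, _ = concordance_sample(a, b, n=1000, seed=3)
    r2, _ = concordance_sample(a, b, n=1000, seed=3)
    r3, _ = concordance_sample(a, b, n=1000, seed=4)
    assert r1 == r2
    assert r1 != r3  # different sample
    assert r1 > 0.8


def test_concordance_uses_all_when_few_shared(rng):
    a, _ = _platform(rng, n=500)
    r, n = concordance_sample(a, a, n=2000, seed=1)
    assert n == 500 and r == pytest.approx(1.0)
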