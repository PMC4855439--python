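"""CpG-island detection (vs brute-force oracle), classification, Fisher testing."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from methylome.cgi import (
    bonferroni,
    cgi_summary,
    classify_cgi,
    fisher_exact_2x2,
    predict_cgis,
    CpGIsland,
)
from methylome.cgi import test_cgi as run_island_test
from methylome.cgi import test_cgis as run_island_tests
from methylome.model import GeneModel
from methylome.sites import SiteIndex

from conftest import make_sites


# ---------------------------------------------------------------------------
# brute-force oracle for the island detector
# ---------------------------------------------------------------------------

def brute_force_cgis(seq, window=100, minlen=200, min_oe=0.6, min_gc=50.0):
    """O(n·w) reference: per-window pass/fail with string counting, run merge."""
    passing = []
    for i in range(len(seq) - window + 1):
        w = seq[i : i + window]
        nc, ng = w.count("C"), w.count("G")
        ncpg = w.count("CG")
        if nc * ng == 0:
            continue
        oe = ncpg * window / (nc * ng)
        gc = 100.0 * (nc + ng) / window
        if oe >= min_oe and gc >= min_gc:
            passing.append(i)
    islands = []
    run = []
    for i in passing + [None]:
        if run and (i is None or i != run[-1] + 1):
            s, e = run[0], run[-1] + window
            if e - s >= minlen:
                islands.append((s, e))
            run = []
        if i is not None:
            run.append(i)
    return islands


def test_cg_repeat_is_one_island():
    seq = "CG" * 150
    islands = predict_cgis(seq)
    assert [(i.start, i.end) for i in islands] == [(0, 300)]
    # every window: N_C = N_G = 50, N_CpG = 50 -> O/E = 2.0, GC = 100 %
    assert islands[0].obs_exp == pytest.approx(2.0)
    assert islands[0].gc_pct == pytest.approx(100.0)


def test_at_repeat_has_no_islands():
    assert predict_cgis("AT" * 500) == []


def test_short_dense_block_below_minlen_dropped(rng):
    # a sub-window dense block: passing windows overhang it by < minlen total
    flank = "".join(rng.choice(list("AT"), size=400))
    seq = flank + "CG" * 45 + flank  # 90 bp dense block -> candidate 180 bp
    assert predict_cgis(seq) == []


def test_sequence_shorter_than_window():
    assert predict_cgis("CG" * 20) == []


@pytest.mark.parametrize("seed", range(8))
def test_detector_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    # patchy composition so islands actually occur
    chunks = []
    for _ in range(20):
        if rng.random() < 0.3:
            n = int(rng.integers(100, 400))
            c = rng.choice(list("ACGT"), p=[0.15, 0.35, 0.35, 0.15], size=n)
        else:
            n = int(rng.integers(100, 400))
            c = rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=n)
        chunks.append("".join(c))
    seq = "".join(chunks)[:5000]
    got = [(i.start, i.end) for i in predict_cgis(seq)]
    assert got == brute_force_cgis(seq)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _gene(id, strand, start, end):
    return GeneModel(id, "chr1", strand, start, end, [(start, end)])


def test_classify_promoter_overlap():
    g = _gene("g1", "+", 10_000, 20_000)  # tss 10000, window [8000, 10501)
    isl = CpGIsland("chr1", 9_900, 10_100, 1.0, 60.0)
    assert classify_cgi(isl, [g]).location == "promoter"
    assert isl.genes == ["g1"]


def test_classify_intragenic_beyond_promoter_window():
    g = _gene("g1", "+", 10_000, 30_000)
    isl = CpGIsland("chr1", 15_000, 15_400, 1.0, 60.0)  # deep inside the body
    assert classify_cgi(isl, [g]).location == "intragenic"
    # island fully covering a tiny gene is intragenic too
    tiny = _gene("g2", "+", 50_000, 50_200)
    isl2 = CpGIsland("chr1", 49_000, 52_000, 1.0, 60.0)
    # (but only if it does not overlap the promoter window; use a minus-strand
    # gene whose promoter window lies on the high side)
    assert classify_cgi(isl2, [tiny]).location == "promoter"  # window overlaps here


def test_classify_promoter_precedence_and_intergenic():
    ga = _gene("gA", "+", 10_000, 20_000)
    gb = _gene("gB", "+", 2_000, 9_000)
    isl = CpGIsland("chr1", 8_500, 8_900, 1.0, 60.0)  # inside gB, in gA's window
    assert classify_cgi(isl, [ga, gb]).location == "promoter"
    assert isl.genes == ["gA"]
    far = CpGIsland("chr1", 500_000, 500_300, 1.0, 60.0)
    assert classify_cgi(far, [ga, gb]).location == "intergenic"
    assert far.genes == []


def test_classify_minus_strand_window():
    g = _gene("g1", "-", 10_000, 20_000)  # tss 19999, window [19499, 22000]
    assert classify_cgi(CpGIsland("chr1", 21_000, 21_300, 1, 60), [g]).location == "promoter"
    assert classify_cgi(CpGIsland("chr1", 15_000, 15_300, 1, 60), [g]).location == "intragenic"


# ---------------------------------------------------------------------------
# Fisher exact + Bonferroni
# ---------------------------------------------------------------------------

def fisher_enumeration(table):
    """Exact-fraction enumeration of all tables with the observed margins."""
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c
    def prob(x):
        return (
            Fraction(math.comb(r1, x) * math.comb(n - r1, c1 - x), math.comb(n, c1))
        )
    p_obs = prob(a)
    total = sum(
        (p := prob(x))
        for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
        if prob(x) <= p_obs
    )
    return float(total)


def test_fisher_identical_tables():
    assert fisher_exact_2x2(((10, 5), (10, 5))) == pytest.approx(1.0)


def test_fisher_extreme_table():
    # [[10,0],[0,10]]: only the two extreme tables are as unlikely -> 2/C(20,10)
    assert fisher_exact_2x2(((10, 0), (0, 10))) == pytest.approx(2 / math.comb(20, 10))
    assert fisher_exact_2x2(((10, 0), (0, 10))) == pytest.approx(1.0824e-5, rel=1e-3)


@pytest.mark.parametrize("seed", range(30))
def test_fisher_matches_enumeration_and_scipy(seed):
    rng = np.random.default_rng(seed)
    t = tuple(tuple(int(x) for x in row) for row in rng.integers(0, 21, (2, 2)))
    if sum(map(sum, t)) == 0:
        t = ((1, 0), (0, 1))
    p = fisher_exact_2x2(t)
    assert p == pytest.approx(fisher_enumeration(t), rel=1e-9)
    assert p == pytest.approx(stats.fisher_exact(t).pvalue, rel=1e-6)


def test_fisher_rejects_negative():
    with pytest.raises(ValueError):
        fisher_exact_2x2(((-1, 2), (3, 4)))


def test_bonferroni():
    assert bonferroni([0.001], m=10).tolist() == [0.01]
    assert bonferroni([0.5], m=10).tolist() == [1.0]
    assert bonferroni([0.2]).tolist() == [0.2]  # m = 1 is the identity
    with pytest.raises(ValueError):
        bonferroni([1.5])


# ---------------------------------------------------------------------------
# island testing machinery
# ---------------------------------------------------------------------------

def _cpg_index(pos_levels, depth=30):
    recs = [("chr1", p, "+", "CpG", "CpG", round(l * depth), depth) for p, l in pos_levels]
    return SiteIndex(make_sites(recs))


def test_island_with_too_few_sites_excluded_from_m():
    isl_ok = CpGIsland("chr1", 0, 100, 1, 60)
    isl_small = CpGIsland("chr1", 200, 300, 1, 60)
    ia = _cpg_index([(10, 0.1), (20, 0.2), (30, 0.3), (250, 0.5), (260, 0.5)])
    ib = _cpg_index([(10, 0.1), (20, 0.2), (30, 0.3), (250, 0.5), (260, 0.5)])
    assert run_island_test(isl_small, ia, ib) is None  # 2 sites < 3
    results = run_island_tests([isl_ok, isl_small], ia, ib)
    assert len(results) == 1  # m = 1: q equals p
    assert results[0].q == pytest.approx(results[0].p)


def test_identical_tissues_not_significant():
    ia = _cpg_index([(10, 0.2), (20, 0.4), (30, 0.6)])
    r = run_island_test(CpGIsland("chr1", 0, 100, 1, 60), ia, ia)
    assert r.p == pytest.approx(1.0)


def test_cgi_summary_percentages():
    islands, results = [], []
    for cls, n in (("promoter", 4), ("intragenic", 3), ("intergenic", 3)):
        for i in range(n):
            isl = CpGIsland("chr1", 1000 * len(islands), 1000 * len(islands) + 300, 1, 60)
            isl.location = cls
            isl.genes = [f"{cls}_g{i}"] if cls != "intergenic" else []
            islands.append(isl)
    table = cgi_summary(islands, [])
    total = table[table["class"] == "Total"].iloc[0]
    prom = table[table["class"] == "promoter"].iloc[0]
    assert total["n_cgis"] == 10
    assert prom["pct_of_total"] == 40.0
    assert prom["n_differential"] == 0 and prom["pct_differential"] == 0.0
    assert (table["n_cgis"][1:].sum()) == total["n_cgis"]  # classes partition
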