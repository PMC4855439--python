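"""Feature derivation, region summaries, window profiles, length deciles."""

import math

import numpy as np
import pytest

from methylome.features import (
    FeatureRegion,
    derive_features,
    length_decile_means,
    merge_transcripts,
    summarize_region,
    window_bounds,
    window_profile,
)
from methylome.model import GeneModel
from methylome.sites import SiteIndex
from methylome.util import merge_intervals, subtract_intervals, total_length

from conftest import make_sites


def gene(id="g", strand="+", start=1000, end=3000, exons=None, **kw):
    return GeneModel(id, "chr1", strand, start, end, exons or [(start, end)], **kw)


# ---------------------------------------------------------------------------
# transcript merging
# ---------------------------------------------------------------------------

def test_merge_identical_boundaries_unions_exons():
    t1 = gene("g.t1", exons=[(1000, 1500), (2000, 3000)])
    t2 = gene("g.t2", exons=[(1000, 1500), (1700, 1800), (2000, 3000)])
    merged = merge_transcripts([t1, t2])
    assert len(merged) == 1
    assert merged[0].exons == [(1000, 1500), (1700, 1800), (2000, 3000)]
    assert merged[0].id == "g"


def test_merge_requires_exact_boundary_equality():
    t1 = gene("a.t1", start=1000, end=3000)
    t2 = gene("b.t1", start=1001, end=3000)  # TSS differs by 1 bp
    assert len(merge_transcripts([t1, t2])) == 2
    assert len(merge_transcripts([t1])) == 1


# ---------------------------------------------------------------------------
# feature derivation
# ---------------------------------------------------------------------------

def test_tss_tts_windows_plus_strand():
    g = gene(start=1000, end=3000)
    f = derive_features(g, 10_000)
    assert f["TSS"].intervals == [(700, 1051)]  # -300/+50 inclusive: 351 bp
    assert f["TSS"].length == 351
    assert f["TTS"].intervals == [(2949, 3200)]  # -50/+200 inclusive: 251 bp
    assert f["TTS"].length == 251
    assert f["GB"].intervals == [(1000, 3000)]
    assert f["upstream10k"].intervals == [(0, 1000)]  # clamped at chromosome start


def test_tss_tts_windows_minus_strand():
    g = gene(strand="-", start=1000, end=3000)  # tss = 2999, tts = 1000
    f = derive_features(g, 10_000)
    assert f["TSS"].intervals == [(2949, 3300)]
    assert f["TTS"].intervals == [(800, 1051)]
    assert f["upstream10k"].intervals == [(3000, 10_000)]


def test_tss_clamped_at_chromosome_start():
    g = gene(start=100, end=1000)
    assert derive_features(g, 10_000)["TSS"].intervals == [(0, 151)]


def test_gb_partition_property():
    exons = [(1000, 1200), (1500, 1900), (2500, 3000)]
    g = gene(exons=exons, utr5=[(1000, 1100)], cds=[(1100, 1200), (1500, 1900), (2500, 2800)],
             utr3=[(2800, 3000)])
    f = derive_features(g, 10_000)
    parts = f["5UTR"].intervals + f["CDS"].intervals + f["3UTR"].intervals + f["intron"].intervals
    assert total_length(parts) == g.length
    assert merge_intervals(parts) == [(1000, 3000)]  # disjoint cover of the GB


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _index(levels, start=0, step=10, context="CpG"):
    dinuc = "CpG" if context == "CpG" else "CpA"
    recs = [
        ("chr1", start + i * step, "+", context, dinuc, round(l * 1000), 1000)
        for i, l in enumerate(levels)
    ]
    return SiteIndex(make_sites(recs))


def test_summarize_region_mean_and_density():
    idx = _index([0.2, 0.4, 0.6])
    region = FeatureRegion("g", "GB", "chr1", "+", [(0, 100)])
    s = summarize_region(region, idx)
    assert s.defined and s.n_sites == 3
    assert s.mean_level == pytest.approx(0.4)
    assert s.density == 1.0  # every level > 0.10


def test_summarize_region_undefined_below_min_sites():
    idx = _index([0.2, 0.4])
    s = summarize_region(FeatureRegion("g", "GB", "chr1", "+", [(0, 100)]), idx, min_sites=3)
    assert not s.defined and math.isnan(s.mean_level)
    assert s.n_sites == 2 and s.density == 1.0  # density defined for any n >= 1


def test_density_threshold_is_strict():
    idx = _index([0.10, 0.101, 0.5])
    s = summarize_region(FeatureRegion("g", "GB", "chr1", "+", [(0, 100)]), idx)
    assert s.density == pytest.approx(2 / 3)  # 0.10 exactly is NOT methylated


def test_summarize_matches_brute_force(rng):
    pos = np.sort(rng.choice(5000, 300, replace=False))
    levels = rng.random(300)
    recs = [("chr1", int(p), "+", "CpG", "CpG", int(round(l * 1000)), 1000)
            for p, l in zip(pos, levels)]
    idx = SiteIndex(make_sites(recs))
    ivs = [(100, 900), (2000, 3500)]
    expect = [m / 1000 for p, l in zip(pos, levels)
              for m in [round(l * 1000)] if any(s <= p < e for s, e in ivs)]
    s = summarize_region(FeatureRegion("g", "GB", "chr1", "+", ivs), idx)
    assert s.n_sites == len(expect)
    assert s.mean_level == pytest.approx(float(np.mean(expect)))


# ---------------------------------------------------------------------------
# window profiles
# ---------------------------------------------------------------------------

def test_window_bounds_overshoot_clamped():
    b = window_bounds(1000, 40, 0.05, 0.025)
    assert b[0] == (0, 50) and b[1] == (25, 75)
    assert b[39] == (975, 1000)  # final window clamped to the region end
    assert all(b[i + 1][0] > b[i][0] for i in range(39))


def test_window_profile_constant_levels():
    idx = _index([0.5] * 100, start=0, step=10)
    region = FeatureRegion("g", "GB", "chr1", "+", [(0, 1000)])
    prof = window_profile(region, idx)
    assert prof.defined and len(prof.windows) == 40
    assert all(w[2] == pytest.approx(0.5) for w in prof.windows)
    starts = [w[0] for w in prof.windows]
    assert starts == sorted(starts) and len(set(starts)) == 40


def test_window_profile_strand_mirror_symmetry(rng):
    """A − strand profile equals the + strand profile of the mirrored sites.

    (Exact sequence reversal does not hold: the clamped final window makes the
    window layout asymmetric, so the invariant is mirror symmetry instead.)
    """
    levels = rng.random(100)
    pos = np.sort(rng.choice(1000, 100, replace=False))
    recs = [("chr1", int(p), "+", "CpG", "CpG", round(l * 1000), 1000)
            for p, l in zip(pos, levels)]
    mirrored = [("chr1", 999 - int(p), "+", "CpG", "CpG", round(l * 1000), 1000)
                for p, l in zip(pos, levels)]
    minus = window_profile(
        FeatureRegion("g", "GB", "chr1", "-", [(0, 1000)]), SiteIndex(make_sites(recs))
    )
    plus_mirror = window_profile(
        FeatureRegion("g", "GB", "chr1", "+", [(0, 1000)]), SiteIndex(make_sites(mirrored))
    )
    a = [w[2] for w in minus.windows]
    b = [w[2] for w in plus_mirror.windows]
    assert a == pytest.approx(b, nan_ok=True)


def test_window_profile_short_region_flagged():
    idx = _index([0.5])
    prof = window_profile(FeatureRegion("g", "GB", "chr1", "+", [(0, 30)]), idx)
    assert not prof.defined and prof.windows == []


# ---------------------------------------------------------------------------
# length deciles
# ---------------------------------------------------------------------------

def _summaries(genes, levels):
    from methylome.features import RegionMethylationSummary

    return {
        g.id: RegionMethylationSummary(g.id, "GB", "CpG", 10, lv, 0.5, True)
        for g, lv in zip(genes, levels)
    }


def test_length_deciles_one_gene_per_bin():
    genes = [gene(f"g{i}", start=0, end=(i + 1) * 1000) for i in range(10)]
    table = length_decile_means(genes, _summaries(genes, [0.3] * 10))
    assert table["n_genes"].tolist() == [1] * 10
    assert table["mean_level"].tolist() == pytest.approx([0.3] * 10)


def test_length_deciles_follow_planted_length_trend(rng):
    lengths = rng.integers(1000, 50_000, 95)
    genes = [gene(f"g{i:03d}", start=0, end=int(l)) for i, l in enumerate(lengths)]
    levels = 0.2 + 0.6 * (lengths - 1000) / 49_000  # level increasing in length
    table = length_decile_means(genes, _summaries(genes, levels))
    assert table["n_genes"].sum() == 95
    assert table["n_genes"].min() >= 9  # remainder spread over the last bins
    diffs = np.diff(table["mean_level"].to_numpy())
    assert (diffs >= 0).all()


def test_length_deciles_require_ten_genes():
    genes = [gene(f"g{i}", start=0, end=1000 + i) for i in range(9)]
    with pytest.raises(ValueError):
        length_decile_means(genes, _summaries(genes, [0.3] * 9))


def test_subtract_intervals():
    assert subtract_intervals((0, 100), [(10, 20), (50, 60)]) == [(0, 10), (20, 50), (60, 100)]
    assert subtract_intervals((0, 100), []) == [(0, 100)]
    assert subtract_intervals((0, 100), [(0, 100)]) == []
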