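"""Between-tissue differential methylation of gene features.

Genes are ranked per feature by the log2 fold change of their mean methylation
levels between two tissues (with a small pseudocount, since levels can be 0).
Features where the two levels sum to at most 10 % (hypomethylated in both
tissues) or where either tissue covers fewer than 3 sites are filtered out;
the upper and lower 2.5 % tails of the remaining fold-change distribution form
the hyper-/hypomethylated gene sets.  Expression contrasts between sets use a
pooled-variance two-sample t-test; methylation-expression association uses
mid-rank Spearman / product-moment Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DifferentialGeneResult:
    gene_id: str
    kind: str
    level_a: float
    level_b: float
    fold_change: float  # NaN when filtered
    category: str  # hyper_in_a / hypo_in_a / not_extreme / filtered


def fold_change(level_a: float, level_b: float, eps: float = 0.01) -> float:
    """log2((level_a + eps) / (level_b + eps)); eps guards zero levels."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    return math.log2((level_a + eps) / (level_b + eps))


def differential_table(
    summaries_a,
    summaries_b,
    kind: str,
    eps: float = 0.01,
    min_sum_level: float = 0.10,
) -> list[DifferentialGeneResult]:
    """Join two tissues' per-gene summaries of one feature into results.

    ``summaries_a/b`` map gene id -> RegionMethylationSummary for the feature.
    A gene is ``filtered`` when either summary is undefined (< min_sites
    covered sites) or when level_a + level_b <= ``min_sum_level``, i.e. only
    features whose two tissue levels sum to strictly more than 10 % are
    ranked."""
    out = []
    for gid in sorted(set(summaries_a) & set(summaries_b)):
        sa, sb = summaries_a[gid], summaries_b[gid]
        if not (sa.defined and sb.defined) or (sa.mean_level + sb.mean_level) <= min_sum_level:
            out.append(DifferentialGeneResult(gid, kind, sa.mean_level, sb.mean_level,
                                              math.nan, "filtered"))
        else:
            fc = fold_change(sa.mean_level, sb.mean_level, eps)
            out.append(DifferentialGeneResult(gid, kind, sa.mean_level, sb.mean_level,
                                              fc, "not_extreme"))
    return out


def select_extremes(
    results: list[DifferentialGeneResult], tail_fraction: float = 0.025
) -> tuple[list[str], list[str]]:
    """Upper/lower fold-change tails among non-filtered genes.

    Each tail holds ``floor(tail_fraction * n_passing)`` genes; ties broken by
    gene id so the two sets are disjoint and deterministic.  Results are
    relabelled in place (hyper_in_a / hypo_in_a).
    """
    if not 0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5)")
    passing = [r for r in results if r.category != "filtered"]
    k = math.floor(tail_fraction * len(passing))
    passing.sort(key=lambda r: (r.fold_change, r.gene_id))
    hypo = passing[:k]
    hyper = passing[len(passing) - k :] if k else []
    for r in hyper:
        r.category = "hyper_in_a"
    for r in hypo:
        r.category = "hypo_in_a"
    return [r.gene_id for r in hyper], [r.gene_id for r in hypo]


@dataclass(frozen=True)
class PercentileGrouping:
    gene_id: str
    kind: str
    group: int  # 1..n_groups


def noncpg_percentile_groups(
    summaries, kind: str, n_groups: int = 40
) -> list[PercentileGrouping]:
    """Equal-count percentile groups of genes by non-CpG mean level.

    ``summaries`` maps gene id -> defined RegionMethylationSummary.  Genes are
    sorted ascending by level (ties by id) and split into ``n_groups`` groups;
    remainder genes go to the highest groups.  Groups 1 and ``n_groups`` are
    the differential (lowest / highest methylation) sets.
    """
    items = sorted(
        ((s.mean_level, gid) for gid, s in summaries.items() if s.defined),
    )
    if len(items) < n_groups:
        raise ValueError(f"need at least {n_groups} genes, got {len(items)}")
    base, rem = divmod(len(items), n_groups)
    sizes = [base] * (n_groups - rem) + [base + 1] * rem
    out, i = [], 0
    for g, size in enumerate(sizes, 1):
        out.extend(PercentileGrouping(gid, kind, g) for _, gid in items[i : i + size])
        i += size
    return out


def expression_ttest(fpkm_a, fpkm_b) -> tuple[float, float]:
    """Pooled-variance two-sample t-test (df = n_a + n_b − 2), two-sided p.

    Degenerate zero-variance inputs: equal means give (0, 1); unequal means
    give (±inf, 0).
    """
    a = np.asarray(fpkm_a, float)
    b = np.asarray(fpkm_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite expression values")
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rho on mid-ranks with two-sided p; zero variance -> (nan, nan)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def linear_correlation(x, y) -> tuple[float, float]:
    """Pearson product-moment r with two-sided p; zero variance -> (nan, nan)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def concordance_sample(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    n: int = 2000,
    seed: int = 0,
    min_depth_exclusive: int = 10,
) -> tuple[float, int]:
    """Cross-platform agreement: Pearson r of levels at sampled shared CpGs.

    Shared CpG sites with coverage strictly above ``min_depth_exclusive`` in
    both tables are sampled uniformly without replacement (seed-deterministic);
    if fewer than ``n`` shared sites exist all are used.  Returns (r, n_used).
    """
    def keyed(df):
        sub = df[(df["context"] == "CpG") & (df["n_total"] > min_depth_exclusive)]
        return sub.set_index(["chrom", "pos", "strand"])["level"]

    a, b = keyed(sites_a), keyed(sites_b)
    shared = a.index.intersection(b.index).sort_values()
    if len(shared) > n:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(shared), size=n, replace=False)
        shared = shared[np.sort(pick)]
    r, _ = linear_correlation(a.loc[shared].to_numpy(), b.loc[shared].to_numpy())
    return r, len(shared)
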