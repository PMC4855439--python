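"""CpG-island prediction, genomic classification and differential testing.

Islands are detected with the classic observed/expected-CpG rule: a 100 bp
window sliding by 1 bp passes when O/E = (N_CpG · w) / (N_C · N_G) >= 0.6 and
GC >= 50 %; maximal runs of consecutive passing window starts merge into a
candidate spanning from the first passing window's start to the last one's
end, and candidates of at least 200 bp are reported with O/E and GC recomputed
over the full island.  No decade-averaging smoothing is applied; the detector
is defined exactly by this window rule (and tested against a brute-force
oracle).

Differential methylation per island pools methylated/unmethylated read counts
over the island's covered CpG sites in each tissue into a 2x2 table, tested
with a two-sided Fisher exact test (point-probability summation) and
Bonferroni-corrected over the islands actually tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .model import GeneModel
from .sites import SiteIndex
from .util import pct


@dataclass
class CpGIsland:
    chrom: str
    start: int
    end: int
    obs_exp: float
    gc_pct: float
    location: str | None = None  # promoter / intragenic / intergenic
    genes: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def _window_stats(nc: int, ng: int, ncpg: int, length: int) -> tuple[float, float]:
    gc = 100.0 * (nc + ng) / length
    oe = (ncpg * length) / (nc * ng) if nc * ng > 0 else math.nan
    return oe, gc


def predict_cgis(
    sequence: str,
    chrom: str = "seq",
    window: int = 100,
    minlen: int = 200,
    min_oe: float = 0.6,
    min_gc: float = 50.0,
) -> list[CpGIsland]:
    """Detect CpG islands in one sequence (parameters mirror cpgplot defaults)."""
    L = len(sequence)
    if L < window:
        return []
    a = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    isc = (a == ord("C")).astype(np.int64)
    isg = (a == ord("G")).astype(np.int64)
    iscg = np.zeros(L, np.int64)
    iscg[:-1] = isc[:-1] & (a[1:] == ord("G"))
    cc, cg_, ccg = (np.concatenate(([0], np.cumsum(x))) for x in (isc, isg, iscg))

    starts = np.arange(L - window + 1)
    nc = cc[starts + window] - cc[starts]
    ng = cg_[starts + window] - cg_[starts]
    # CpG dinucleotides fully inside the window: starts in [i, i+w-1)
    ncpg = ccg[starts + window - 1] - ccg[starts]
    denom = nc * ng
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(denom > 0, ncpg * window / np.maximum(denom, 1), np.nan)
    gc = 100.0 * (nc + ng) / window
    passing = (denom > 0) & (oe >= min_oe) & (gc >= min_gc)

    islands: list[CpGIsland] = []
    idx = np.flatnonzero(passing)
    if len(idx) == 0:
        return islands
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([0], breaks + 1))
    run_ends = np.concatenate((breaks, [len(idx) - 1]))
    for rs, re in zip(run_starts, run_ends):
        s = int(idx[rs])
        e = int(idx[re]) + window
        if e - s >= minlen:
            n_c = int(cc[e] - cc[s])
            n_g = int(cg_[e] - cg_[s])
            n_cpg = int(ccg[e - 1] - ccg[s])
            oe_i, gc_i = _window_stats(n_c, n_g, n_cpg, e - s)
            islands.append(CpGIsland(chrom, s, e, oe_i, gc_i))
    return islands


def predict_cgis_genome(genome: dict[str, str], **kw) -> list[CpGIsland]:
    out = []
    for chrom, seq in genome.items():
        out.extend(predict_cgis(seq, chrom=chrom, **kw))
    return out


def classify_cgi(
    island: CpGIsland,
    genes: list[GeneModel],
    promoter_up: int = 2000,
    promoter_down: int = 500,
) -> CpGIsland:
    """Assign one location class with precedence promoter > intragenic > intergenic.

    Promoter: the island overlaps a gene's strand-aware window from
    ``promoter_up`` bp upstream to ``promoter_down`` bp downstream of its TSS
    (both offsets inclusive).  Intragenic: the island lies within a gene span
    or fully covers one.  ``island.genes`` lists all genes triggering the
    assigned class.
    """
    promoter_hits, intragenic_hits = [], []
    for g in genes:
        if g.chrom != island.chrom:
            continue
        t = g.tss
        if g.strand == "+":
            win = (t - promoter_up, t + promoter_down + 1)
        else:
            win = (t - promoter_down, t + promoter_up + 1)
        if island.start < win[1] and island.end > win[0]:
            promoter_hits.append(g.id)
        elif (island.start >= g.start and island.end <= g.end) or (
            island.start <= g.start and island.end >= g.end
        ):
            intragenic_hits.append(g.id)
    if promoter_hits:
        island.location, island.genes = "promoter", sorted(promoter_hits)
    elif intragenic_hits:
        island.location, island.genes = "intragenic", sorted(intragenic_hits)
    else:
        island.location, island.genes = "intergenic", []
    return island


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p by hypergeometric point-probability summation.

    All tables with the observed margins whose point probability does not
    exceed the observed table's (within a small relative tolerance) contribute
    to p.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative count in 2x2 table")
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    if n == 0:
        return 1.0
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(1.0, p)


@dataclass
class CGITestResult:
    island: CpGIsland
    n_sites_a: int
    n_sites_b: int
    counts: tuple[tuple[int, int], tuple[int, int]]  # [[meth_a, unmeth_a], [meth_b, unmeth_b]]
    level_a: float  # pooled fraction methylated reads, tissue A
    level_b: float
    p: float
    q: float = math.nan
    direction: str = ""
    significant: bool = False


def test_cgi(
    island: CpGIsland, index_a: SiteIndex, index_b: SiteIndex, min_sites: int = 3
) -> CGITestResult | None:
    """Fisher test of pooled CpG read counts in one island between tissues.

    Returns None (island excluded from testing and from the Bonferroni m) when
    either tissue covers fewer than ``min_sites`` CpG sites in the island.
    """
    iv = [(island.start, island.end)]
    na, ma, ta = index_a.pooled_counts(island.chrom, iv, "CpG")
    nb, mb, tb = index_b.pooled_counts(island.chrom, iv, "CpG")
    if na < min_sites or nb < min_sites:
        return None
    table = ((ma, ta - ma), (mb, tb - mb))
    p = fisher_exact_2x2(table)
    la = ma / ta if ta else math.nan
    lb = mb / tb if tb else math.nan
    direction = "hyper_in_a" if la >= lb else "hypo_in_a"
    return CGITestResult(island, na, nb, table, la, lb, p, direction=direction)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """q_i = min(1, p_i * m); m defaults to the number of p-values."""
    p = np.asarray(p_values, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(1.0, p * m)


def test_cgis(
    islands: list[CpGIsland],
    index_a: SiteIndex,
    index_b: SiteIndex,
    min_sites: int = 3,
    q_cutoff: float = 0.05,
) -> list[CGITestResult]:
    """Test every eligible island; Bonferroni m = number of islands tested."""
    results = [r for isl in islands if (r := test_cgi(isl, index_a, index_b, min_sites))]
    qs = bonferroni([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
        r.significant = q <= q_cutoff
    return results


def cgi_summary(islands: list[CpGIsland], results: list[CGITestResult]) -> pd.DataFrame:
    """Class-wise island counts, differential counts and percentages.

    One row per location class plus a Total row: number of islands, % of the
    total, differential islands (q significant), % differential within class,
    hyper/hypo (in tissue A) splits and unique associated genes.
    """
    by_class: dict[str, dict] = {}
    for cls in ("promoter", "intragenic", "intergenic"):
        members = [i for i in islands if i.location == cls]
        res = [r for r in results if r.island.location == cls]
        sig = [r for r in res if r.significant]
        genes = sorted({g for i in members for g in i.genes})
        by_class[cls] = {
            "n": len(members),
            "n_diff": len(sig),
            "n_hyper_a": sum(1 for r in sig if r.direction == "hyper_in_a"),
            "n_hypo_a": sum(1 for r in sig if r.direction == "hypo_in_a"),
            "n_genes": len(genes),
        }
    total = {k: sum(v[k] for v in by_class.values()) for k in next(iter(by_class.values()))}
    total["n_genes"] = len({g for i in islands for g in i.genes})
    rows = []
    for name, d in [("Total", total)] + list(by_class.items()):
        rows.append(
            {
                "class": name,
                "n_cgis": d["n"],
                "pct_of_total": pct(d["n"], total["n"], 1) if total["n"] else math.nan,
                "n_differential": d["n_diff"],
                "pct_differential": pct(d["n_diff"], d["n"], 1) if d["n"] else 0.0,
                "n_hyper_in_a": d["n_hyper_a"],
                "n_hypo_in_a": d["n_hypo_a"],
                "n_associated_genes": d["n_genes"],
            }
        )
    return pd.DataFrame(rows)
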