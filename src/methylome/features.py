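"""Gene feature regions, per-region methylation summaries and window profiles.

Each gene contributes a set of strand-aware derived regions:

* TSS: 300 bp upstream to 50 bp downstream of the transcription start (351 bp,
  both offsets inclusive, clamped at chromosome bounds);
* TTS: 50 bp upstream to 200 bp downstream of the termination site (251 bp);
* GB: the full annotated gene span, plus its 5'UTR / CDS / intron / 3'UTR
  partition;
* 10 kb upstream/downstream flanks.

Region methylation is the unweighted mean of per-site levels (pooling read
counts would weight sites by coverage); a region with fewer covered sites than
``min_sites`` is reported as undefined.  Metagene profiles cut each region into
40 sliding windows of 5 % of the region length every 2.5 %, the final window
clamped to the region end, reported 5'→3' in gene orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import GeneModel
from .sites import SiteIndex
from .util import merge_intervals, subtract_intervals, total_length

FEATURE_KINDS = (
    "TSS", "5UTR", "CDS", "intron", "3UTR", "GB", "TTS", "upstream10k", "downstream10k",
)


@dataclass
class FeatureRegion:
    gene_id: str
    kind: str
    chrom: str
    strand: str
    intervals: list[tuple[int, int]]

    @property
    def length(self) -> int:
        return total_length(self.intervals)


@dataclass
class RegionMethylationSummary:
    gene_id: str
    kind: str
    context: str
    n_sites: int
    mean_level: float  # NaN when undefined
    density: float  # fraction of sites with level > threshold; NaN if no sites
    defined: bool


@dataclass
class WindowProfile:
    gene_id: str
    kind: str
    windows: list[tuple[float, float, float, int]] = field(default_factory=list)
    defined: bool = True


def merge_transcripts(transcripts: list[GeneModel]) -> list[GeneModel]:
    """Collapse transcripts sharing (chrom, strand, tss, tts) into one gene.

    The merged gene keeps the exon union (overlaps merged); CDS/UTR interval
    sets are unioned the same way.  Input order of first appearance is kept.
    """
    merged: dict[tuple, GeneModel] = {}
    for t in transcripts:
        key = (t.chrom, t.strand, t.tss, t.tts)
        if key not in merged:
            merged[key] = GeneModel(
                id=t.id.split(".t")[0],
                chrom=t.chrom,
                strand=t.strand,
                start=t.start,
                end=t.end,
                exons=list(t.exons),
                cds=list(t.cds),
                utr5=list(t.utr5),
                utr3=list(t.utr3),
            )
        else:
            g = merged[key]
            g.exons = merge_intervals(g.exons + t.exons)
            g.cds = merge_intervals(g.cds + t.cds)
            g.utr5 = merge_intervals(g.utr5 + t.utr5)
            g.utr3 = merge_intervals(g.utr3 + t.utr3)
    return list(merged.values())


def _clamp(s: int, e: int, bound: int) -> tuple[int, int]:
    return max(0, s), min(bound, e)


def derive_features(
    gene: GeneModel, chrom_length: int, flank: int = 10_000
) -> dict[str, FeatureRegion]:
    """Derive all feature regions of one gene (clamped, never failing)."""
    t, e = gene.tss, gene.tts
    if gene.strand == "+":
        tss = (t - 300, t + 51)
        tts = (e - 50, e + 201)
        up = (gene.start - flank, gene.start)
        down = (gene.end, gene.end + flank)
    else:
        tss = (t - 50, t + 301)
        tts = (e - 200, e + 51)
        up = (gene.end, gene.end + flank)
        down = (gene.start - flank, gene.start)
    exons = merge_intervals(gene.exons)
    introns = subtract_intervals((gene.start, gene.end), exons)
    regions = {
        "TSS": [_clamp(*tss, chrom_length)],
        "TTS": [_clamp(*tts, chrom_length)],
        "GB": [(gene.start, gene.end)],
        "5UTR": gene.utr5,
        "CDS": gene.cds,
        "3UTR": gene.utr3,
        "intron": introns,
        "upstream10k": [_clamp(*up, chrom_length)],
        "downstream10k": [_clamp(*down, chrom_length)],
    }
    return {
        kind: FeatureRegion(gene.id, kind, gene.chrom, gene.strand,
                            [iv for iv in ivs if iv[1] > iv[0]])
        for kind, ivs in regions.items()
    }


def summarize_region(
    region: FeatureRegion,
    index: SiteIndex,
    context: str = "CpG",
    min_sites: int = 3,
    methylated_threshold: float = 0.10,
) -> RegionMethylationSummary:
    """Unweighted mean level and methylation density over a region.

    Sites on both strands contribute (regions are strand-derived but site
    inclusion is not strand-filtered).  ``density`` is the fraction of covered
    sites with level strictly above the threshold.
    """
    levels = index.levels(region.chrom, region.intervals, context)
    n = len(levels)
    defined = n >= min_sites
    mean = float(levels.mean()) if defined else math.nan
    density = float((levels > methylated_threshold).mean()) if n else math.nan
    return RegionMethylationSummary(region.gene_id, region.kind, context, n, mean, density, defined)


def window_bounds(length: int, n_windows: int, width_frac: float, step_frac: float
                  ) -> list[tuple[int, int]]:
    """Integer window bounds on [0, length): window i is
    [floor(i*step*L), floor(i*step*L + width*L)), the last clamped to L."""
    out = []
    for i in range(n_windows):
        lo = math.floor(i * step_frac * length)
        hi = min(length, math.floor(i * step_frac * length + width_frac * length))
        out.append((lo, hi))
    return out


def window_profile(
    region: FeatureRegion,
    index: SiteIndex,
    context: str = "CpG",
    n_windows: int = 40,
    width_frac: float = 0.05,
    step_frac: float = 0.025,
) -> WindowProfile:
    """Sliding-window mean levels across a contiguous region, 5'→3'.

    Only single-interval regions (GB, flanks, TE regions) are profiled.  The
    window layout overshoots the region by half a step; the final window is
    clamped to the region end.  Regions shorter than ``n_windows`` bp are
    flagged undefined.
    """
    if len(region.intervals) != 1:
        raise ValueError("window_profile requires a contiguous region")
    (start, end) = region.intervals[0]
    length = end - start
    if length < n_windows:
        return WindowProfile(region.gene_id, region.kind, [], defined=False)
    got = index.select(region.chrom, [(start, end)], context, columns=("pos", "level"))
    # oriented offset: distance from the region's 5' end in gene orientation
    if region.strand == "+":
        offs = got["pos"].astype(np.int64) - start
    else:
        offs = end - 1 - got["pos"].astype(np.int64)
    order = np.argsort(offs, kind="stable")
    offs, levels = offs[order], got["level"][order]
    windows = []
    for i, (lo, hi) in enumerate(window_bounds(length, n_windows, width_frac, step_frac)):
        a, b = np.searchsorted(offs, (lo, hi))
        n = int(b - a)
        mean = float(levels[a:b].mean()) if n else math.nan
        windows.append((i * step_frac, min(1.0, i * step_frac + width_frac), mean, n))
    return WindowProfile(region.gene_id, region.kind, windows)


def length_decile_means(
    genes: list[GeneModel], summaries: dict[str, RegionMethylationSummary], n_bins: int = 10
) -> pd.DataFrame:
    """Mean gene-body methylation by gene-length decile.

    Genes (with a defined GB summary in ``summaries``, keyed by gene id) are
    sorted by GB length, split into ``n_bins`` equal-count bins (remainder
    genes go to the last bins, ties stable by gene id).  Returns one row per
    bin with its gene count, mean length and mean of gene-level mean levels.
    """
    usable = [g for g in genes if g.id in summaries and summaries[g.id].defined]
    if len(usable) < n_bins:
        raise ValueError(f"need at least {n_bins} genes with defined summaries")
    usable.sort(key=lambda g: (g.length, g.id))
    n = len(usable)
    base, rem = divmod(n, n_bins)
    sizes = [base] * (n_bins - rem) + [base + 1] * rem
    rows, i = [], 0
    for b, size in enumerate(sizes, 1):
        chunk = usable[i : i + size]
        i += size
        rows.append(
            {
                "bin": b,
                "n_genes": size,
                "mean_length": float(np.mean([g.length for g in chunk])),
                "mean_level": float(np.mean([summaries[g.id].mean_level for g in chunk])),
            }
        )
    return pd.DataFrame(rows)
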