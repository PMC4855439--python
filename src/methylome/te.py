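"""Transposable-element methylation profiles and expression coupling.

Each TE of at least 500 bp contributes three regions — the body and 2 kb
upstream/downstream flanks (strand-aware; TEs without strand are treated as
+) — each profiled with 10 sliding windows of 20 % of the region length every
10 %, the final window clamped.  Expression coupling is the mid-rank Spearman
correlation between TE FPKM and the region-mean methylation level, reported
separately per region and context, together with the mean level among active
(FPKM > 0) and inactive TEs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import rank_correlation
from .features import FeatureRegion, WindowProfile, summarize_region, window_profile
from .model import TERecord
from .sites import SiteIndex

TE_REGIONS = ("upstream2k", "body", "downstream2k")


def filter_tes(tes: list[TERecord], min_len: int = 500) -> list[TERecord]:
    """Exclude TEs shorter than ``min_len`` bp."""
    return [t for t in tes if t.length >= min_len]


def te_regions(te: TERecord, chrom_length: int, flank: int = 2000) -> dict[str, FeatureRegion]:
    """Body and strand-aware flank regions of one TE, clamped at chromosome ends."""
    if te.strand == "+":
        up = (te.start - flank, te.start)
        down = (te.end, te.end + flank)
    else:
        up = (te.end, te.end + flank)
        down = (te.start - flank, te.start)
    out = {}
    for name, (s, e) in (("upstream2k", up), ("body", (te.start, te.end)), ("downstream2k", down)):
        s, e = max(0, s), min(chrom_length, e)
        out[name] = FeatureRegion(te.id, name, te.chrom, te.strand, [(s, e)] if e > s else [])
    return out


def te_profiles(
    te: TERecord,
    index: SiteIndex,
    chrom_length: int,
    context: str = "nonCpG",
    n_windows: int = 10,
) -> dict[str, WindowProfile]:
    """10-window methylation profile of each TE region, 5'→3' in TE orientation."""
    out = {}
    for name, region in te_regions(te, chrom_length).items():
        if not region.intervals:
            out[name] = WindowProfile(te.id, name, [], defined=False)
            continue
        out[name] = window_profile(
            region, index, context, n_windows=n_windows, width_frac=0.20, step_frac=0.10
        )
    return out


def te_region_means(
    tes: list[TERecord],
    index: SiteIndex,
    chrom_lengths: dict[str, int],
    context: str = "nonCpG",
    min_sites: int = 3,
) -> pd.DataFrame:
    """Per-TE mean methylation level of each region (NaN when undefined)."""
    rows = []
    for te in tes:
        row: dict = {"id": te.id, "fpkm": te.fpkm}
        for name, region in te_regions(te, chrom_lengths[te.chrom]).items():
            if region.intervals:
                s = summarize_region(region, index, context, min_sites=min_sites)
                row[name] = s.mean_level if s.defined else math.nan
            else:
                row[name] = math.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class TECorrelation:
    region: str
    context: str
    rho: float
    p: float
    n_te: int
    mean_level_active: float
    mean_level_inactive: float


def te_expression_correlation(
    means: pd.DataFrame, context: str, min_te: int = 10
) -> list[TECorrelation]:
    """Spearman rho of FPKM against region-mean level, per TE region.

    ``means`` is :func:`te_region_means` output restricted to one context;
    TEs lacking FPKM or a defined level are dropped per region.  Also reports
    mean levels among active (FPKM > 0) and inactive TEs.
    """
    out = []
    for region in TE_REGIONS:
        sub = means.dropna(subset=["fpkm", region])
        if len(sub) < min_te:
            raise ValueError(f"need >= {min_te} TEs with expression and level in {region}")
        rho, p = rank_correlation(sub["fpkm"].to_numpy(), sub[region].to_numpy())
        active = sub["fpkm"] > 0
        out.append(
            TECorrelation(
                region=region,
                context=context,
                rho=rho,
                p=p,
                n_te=len(sub),
                mean_level_active=float(sub.loc[active, region].mean()) if active.any() else math.nan,
                mean_level_inactive=float(sub.loc[~active, region].mean()) if (~active).any() else math.nan,
            )
        )
    return out
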