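"""Non-CpG dinucleotide summaries and sequence-context (motif) matrices.

A site is called methylated when its level is strictly above 10 %, the
convention used for all densities and shares.  Motif matrices count the bases
from 3 bp upstream to 5 bp downstream of a methylated cytosine on its own
strand (reverse-complemented for − strand sites) and report per-position
information content IC = 2 + Σ_b p_b log2 p_b bits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .util import pct

log = logging.getLogger(__name__)

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def dinucleotide_summary(sites: pd.DataFrame, methylated_threshold: float = 0.10) -> pd.DataFrame:
    """Per-dinucleotide non-CpG methylation summary (CpA/CpT/CpC + Total).

    ``mean_level_pct`` averages over all covered sites of the dinucleotide;
    methylated counts (level > threshold) are split by CHG/CHH context.
    """
    non = sites[sites["context"] != "CpG"]
    meth = non["level"] > methylated_threshold
    rows = []
    for dinuc in ("CpA", "CpT", "CpC"):
        sel = non["dinuc"] == dinuc
        rows.append(
            {
                "dinuc": dinuc,
                "n_covered": int(sel.sum()),
                "mean_level_pct": float(non.loc[sel, "level"].mean() * 100) if sel.any() else math.nan,
                "n_meth_CHG": int((sel & meth & (non["context"] == "CHG")).sum()),
                "n_meth_CHH": int((sel & meth & (non["context"] == "CHH")).sum()),
            }
        )
    rows.append(
        {
            "dinuc": "Total",
            "n_covered": int(len(non)),
            "mean_level_pct": float(non["level"].mean() * 100) if len(non) else math.nan,
            "n_meth_CHG": int((meth & (non["context"] == "CHG")).sum()),
            "n_meth_CHH": int((meth & (non["context"] == "CHH")).sum()),
        }
    )
    return pd.DataFrame(rows)


def dinucleotide_shares(summary: pd.DataFrame, ndigits: int = 0) -> dict[str, float]:
    """Shares (%) of methylated non-CpG sites per dinucleotide and per context.

    Works directly from a (possibly externally supplied) count table shaped
    like :func:`dinucleotide_summary` output.
    """
    tot = summary[summary["dinuc"] == "Total"].iloc[0]
    total_meth = int(tot["n_meth_CHG"] + tot["n_meth_CHH"])
    out: dict[str, float] = {}
    for _, row in summary[summary["dinuc"] != "Total"].iterrows():
        d = row["dinuc"]
        out[f"{d}_share_pct"] = pct(int(row["n_meth_CHG"] + row["n_meth_CHH"]), total_meth, ndigits)
        out[f"{d}_share_CHG_pct"] = pct(int(row["n_meth_CHG"]), int(tot["n_meth_CHG"]), ndigits)
        out[f"{d}_share_CHH_pct"] = pct(int(row["n_meth_CHH"]), int(tot["n_meth_CHH"]), ndigits)
    return out


def context_proportions_from_counts(
    methylated: dict[str, int], covered: dict[str, int]
) -> pd.DataFrame:
    """Per-context share of methylated Cs and methylation density from counts.

    ``methylated``/``covered`` map context (CpG/CHG/CHH) to site counts;
    share_c = methylated_c / Σ methylated, density_c = methylated_c /
    covered_c.  Shares are NaN when nothing is methylated.
    """
    total_meth = sum(methylated.values())
    rows = []
    for ctx in ("CpG", "CHG", "CHH"):
        m, c = methylated.get(ctx, 0), covered.get(ctx, 0)
        rows.append(
            {
                "context": ctx,
                "n_covered": c,
                "n_methylated": m,
                "share": m / total_meth if total_meth else math.nan,
                "density": m / c if c else math.nan,
            }
        )
    return pd.DataFrame(rows)


def context_proportions(sites: pd.DataFrame, methylated_threshold: float = 0.10) -> pd.DataFrame:
    """Site-table front end of :func:`context_proportions_from_counts`."""
    meth_mask = sites["level"] > methylated_threshold
    methylated = {
        ctx: int((meth_mask & (sites["context"] == ctx)).sum()) for ctx in ("CpG", "CHG", "CHH")
    }
    covered = {ctx: int((sites["context"] == ctx).sum()) for ctx in ("CpG", "CHG", "CHH")}
    return context_proportions_from_counts(methylated, covered)


@dataclass
class MotifMatrix:
    """Base counts around methylated cytosines, positions −up .. +down."""

    positions: list[int]
    counts: pd.DataFrame  # index positions, columns A/C/G/T
    n_sites: int

    @property
    def information_content(self) -> pd.Series:
        """Per-position IC in bits (2 + Σ p log2 p, with 0·log 0 = 0)."""
        p = self.counts.div(self.counts.sum(axis=1), axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        return pd.Series(2.0 + plogp.sum(axis=1), index=self.counts.index, name="IC")

    def consensus(self) -> str:
        return "".join(self.counts.loc[i].idxmax() for i in self.positions)


def motif_matrix(
    genome: dict[str, str],
    sites: pd.DataFrame,
    context: str,
    up: int = 3,
    down: int = 5,
    methylated_threshold: float = 0.10,
) -> MotifMatrix:
    """Sequence-context matrix around methylated sites of one context class.

    For + strand sites the window is genome[pos−up .. pos+down]; − strand
    windows are reverse-complemented so position 0 is always the methylated C.
    Windows leaving the sequence or containing N are skipped (count logged).
    """
    sel = sites[(sites["context"] == context) & (sites["level"] > methylated_threshold)]
    positions = list(range(-up, down + 1))
    counts = np.zeros((len(positions), 4), np.int64)
    base_idx = {b: i for i, b in enumerate(_BASES)}
    n_used = n_skipped = 0
    for chrom, sub in sel.groupby("chrom", observed=True):
        seq = genome[chrom]
        L = len(seq)
        for pos, strand in zip(sub["pos"].to_numpy(), sub["strand"].to_numpy()):
            if strand == "+":
                s, e = pos - up, pos + down + 1
                if s < 0 or e > L:
                    n_skipped += 1
                    continue
                window = seq[s:e]
            else:
                s, e = pos - down, pos + up + 1
                if s < 0 or e > L:
                    n_skipped += 1
                    continue
                window = seq[s:e].translate(_COMPLEMENT)[::-1]
            if "N" in window:
                n_skipped += 1
                continue
            for j, b in enumerate(window):
                counts[j, base_idx[b]] += 1
            n_used += 1
    if n_skipped:
        log.info("motif_matrix: skipped %d sites with truncated/ambiguous windows", n_skipped)
    frame = pd.DataFrame(counts, index=positions, columns=list(_BASES))
    return MotifMatrix(positions, frame, n_used)
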