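"""Dinucleotide summaries, context proportions and motif matrices."""

import math

import numpy as np
import pytest

from methylome.motifs import (
    context_proportions,
    context_proportions_from_counts,
    dinucleotide_summary,
    dinucleotide_shares,
    motif_matrix,
)

from conftest import make_sites


def test_dinucleotide_summary_single_site():
    sites = make_sites([("c", 5, "+", "CHH", "CpA", 5, 10)])
    t = dinucleotide_summary(sites)
    cpa = t[t["dinuc"] == "CpA"].iloc[0]
    assert cpa["mean_level_pct"] == pytest.approx(50.0)
    assert cpa["n_meth_CHH"] == 1 and cpa["n_meth_CHG"] == 0


def test_dinucleotide_summary_all_unmethylated():
    sites = make_sites(
        [("c", i, "+", "CHH", d, 0, 10) for i, d in enumerate(["CpA", "CpT", "CpC"])]
    )
    t = dinucleotide_summary(sites)
    assert (t["n_meth_CHG"] == 0).all() and (t["n_meth_CHH"] == 0).all()
    assert t[t["dinuc"] == "CpA"]["mean_level_pct"].iloc[0] == 0.0


def test_dinucleotide_row_conservation(rng):
    recs = []
    for i in range(500):
        ctx = ("CHG", "CHH")[i % 2]
        dinuc = ("CpA", "CpT", "CpC")[i % 3]
        total = int(rng.integers(10, 40))
        recs.append(("c", i * 3, "+", ctx, dinuc, int(rng.integers(0, total + 1)), total))
    t = dinucleotide_summary(make_sites(recs))
    tot = t[t["dinuc"] == "Total"].iloc[0]
    body = t[t["dinuc"] != "Total"]
    assert body["n_meth_CHG"].sum() == tot["n_meth_CHG"]
    assert body["n_meth_CHH"].sum() == tot["n_meth_CHH"]
    assert body["n_covered"].sum() == tot["n_covered"]


def test_context_proportions_from_counts():
    t = context_proportions_from_counts(
        {"CpG": 90, "CHG": 5, "CHH": 5}, {"CpG": 100, "CHG": 200, "CHH": 200}
    )
    cpg = t[t["context"] == "CpG"].iloc[0]
    assert cpg["share"] == pytest.approx(0.9)
    assert cpg["density"] == pytest.approx(0.9)
    empty = context_proportions_from_counts({}, {"CpG": 10})
    assert empty["share"].isna().all()


def test_context_proportions_single_methylated_site():
    sites = make_sites(
        [("c", 1, "+", "CpG", "CpG", 9, 10), ("c", 5, "+", "CHH", "CpA", 0, 10)]
    )
    t = context_proportions(sites)
    assert t[t["context"] == "CpG"]["share"].iloc[0] == 1.0


# ---------------------------------------------------------------------------
# motif matrices
# ---------------------------------------------------------------------------

def test_motif_matrix_position_zero_is_all_C():
    #          0123456789
    genome = {"c": "AAACATTTTTT"}
    sites = make_sites([("c", 3, "+", "CHH", "CpA", 8, 10)])
    mm = motif_matrix(genome, sites, "CHH")
    assert mm.n_sites == 1
    assert mm.counts.loc[0, "C"] == 1
    assert mm.information_content[0] == pytest.approx(2.0)
    assert mm.counts.loc[1, "A"] == 1  # immediate 3' base
    assert (mm.counts.sum(axis=1) == mm.n_sites).all()


def test_motif_matrix_skips_truncated_windows():
    genome = {"c": "CATTT"}
    sites = make_sites([("c", 0, "+", "CHH", "CpA", 8, 10)])  # 3 bp upstream missing
    mm = motif_matrix(genome, sites, "CHH")
    assert mm.n_sites == 0


def test_motif_matrix_minus_strand_reverse_complement():
    # minus-strand site at the G: own-strand context reads the complement
    genome = {"c": "AAATTTGTCAAAA"}
    #                      ^ pos 6 is G; minus strand C, 3' bases = comp(T,T)=A,A
    sites = make_sites([("c", 6, "-", "CHH", "CpA", 8, 10)])
    mm = motif_matrix(genome, sites, "CHH")
    assert mm.counts.loc[0, "C"] == 1
    assert mm.counts.loc[1, "A"] == 1
    assert mm.counts.loc[2, "A"] == 1


def test_motif_orientation_invariance(rng):
    """Reverse-complementing the genome and flipping strands leaves the matrix
    unchanged."""
    comp = str.maketrans("ACGT", "TGCA")
    seq = "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=400))
    from methylome.io import classify_contexts_array

    ctx = classify_contexts_array(seq)
    chh = ctx[(ctx["context"] == "CHH")].head(30)
    recs = [("c", int(r.pos), r.strand, "CHH", str(r.dinuc), 9, 10) for r in chh.itertuples()]
    mm1 = motif_matrix({"c": seq}, make_sites(recs), "CHH")
    L = len(seq)
    rc = seq.translate(comp)[::-1]
    flipped = [("c", L - 1 - p, {"+": "-", "-": "+"}[s], c, d, m, t)
               for (c_, p, s, c, d, m, t) in recs]
    mm2 = motif_matrix({"c": rc}, make_sites(flipped), "CHH")
    assert mm1.counts.equals(mm2.counts)


def test_information_content_properties(rng):
    genome = {"c": "".join(rng.choice(list("ACGT"), size=3000))}
    from methylome.io import classify_contexts_array

    ctx = classify_contexts_array(genome["c"])
    chh = ctx[ctx["context"] == "CHH"]
    recs = [("c", int(r.pos), r.strand, "CHH", str(r.dinuc), 9, 10) for r in chh.itertuples()]
    mm = motif_matrix(genome, make_sites(recs), "CHH")
    ic = mm.information_content
    assert ic[0] == pytest.approx(2.0)  # the methylated C itself
    assert ((ic >= 0) & (ic <= 2 + 1e-12)).all()
    # a uniform flanking column tends to 0 bits; position -3 is unconstrained
    assert ic[-3] < 0.05
    # IC is invariant under base relabelling (permutation of the count columns)
    perm = mm.counts[["G", "A", "T", "C"]].copy()
    perm.columns = ["A", "C", "G", "T"]
    from methylome.motifs import MotifMatrix

    mm_perm = MotifMatrix(mm.positions, perm, mm.n_sites)
    assert np.allclose(mm_perm.information_content, ic)


def test_dinucleotide_shares_from_counts():
    import pandas as pd

    summary = pd.DataFrame(
        [
            {"dinuc": "CpA", "n_covered": 0, "mean_level_pct": 0.0,
             "n_meth_CHG": 60, "n_meth_CHH": 90},
            {"dinuc": "CpT", "n_covered": 0, "mean_level_pct": 0.0,
             "n_meth_CHG": 30, "n_meth_CHH": 10},
            {"dinuc": "CpC", "n_covered": 0, "mean_level_pct": 0.0,
             "n_meth_CHG": 10, "n_meth_CHH": 0},
            {"dinuc": "Total", "n_covered": 0, "mean_level_pct": 0.0,
             "n_meth_CHG": 100, "n_meth_CHH": 100},
        ]
    )
    shares = dinucleotide_shares(summary)
    assert shares["CpA_share_pct"] == 75.0
    assert shares["CpA_share_CHG_pct"] == 60.0
    assert shares["CpA_share_CHH_pct"] == 90.0
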