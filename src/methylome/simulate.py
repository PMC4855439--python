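"""Seed-deterministic synthetic two-tissue methylome study.

The generator emits a miniature genome with the statistical structure the
downstream analyses assume, together with the ground truth needed for
recovery tests:

* a CpG-depleted background sequence (O/E ≈ 0.3) with CpG-rich blocks
  (O/E ≥ 0.6, GC ≥ 50 %) embedded at promoters and intergenic positions;
* genes with exon/intron/UTR structure on both strands, some emitted as two
  identical-boundary isoforms to exercise transcript merging;
* transposable elements with 2 kb flanks kept clear of neighbours;
* per-region true CpG levels: hypomethylated TSS/promoter islands,
  gene bodies increasing with gene length, hypermethylated TE bodies
  (stronger in brain), per-site jitter shared between tissues;
* brain-only non-CpG methylation driven by a trinucleotide propensity table
  (CAC > CAG >> other CpA > CpT >> CpC), giving CpA-dominant methylation and
  a CAC-shaped motif; blood non-CpG is a flat ~0.1 % background;
* planted between-tissue differences: gene TSS and GB sets (Δ = 0.4) and
  intergenic CpG islands (Δ = 0.4), all recorded in the truth tables;
* expression negatively coupled to TSS methylation (genes) and to upstream
  non-CpG methylation (TEs, zero-inflated FPKM).

Read counts are Poisson(coverage) per site with binomial methylated reads, so
every measured level carries realistic sampling noise.  One master seed fixes
every emitted byte.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .features import merge_transcripts
from .model import GeneModel, TERecord, finalize_sites

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# RNG stream tags (master seed + tag [+ indices] -> independent deterministic stream)
_T_STRUCT, _T_SEQ, _T_JITTER, _T_NONCPG, _T_READS, _T_EXPR, _T_ANNOT = range(1, 8)


@dataclass
class SyntheticConfig:
    """Study-condition knobs of the generator (defaults are the study design)."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_500_000, "chr2": 1_500_000}
    )
    # genes
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (1500, 8000)
    exon_count_range: tuple[int, int] = (2, 8)
    isoform_fraction: float = 0.10
    # transposable elements
    n_tes: int = 300
    te_length_range: tuple[int, int] = (500, 3000)
    te_short_fraction: float = 0.05  # emitted below the 500 bp analysis cutoff
    te_flank: int = 2000
    # CpG islands
    promoter_cgi_fraction: float = 0.60
    n_intragenic_cgis: int = 60
    n_intergenic_cgis: int = 80
    n_diff_cgis: int = 50  # subset of the intergenic islands, Δ between tissues
    cgi_length_range: tuple[int, int] = (300, 800)
    # sequence composition
    bg_base_probs: tuple[float, ...] = (0.3, 0.2, 0.2, 0.3)  # A C G T
    bg_cpg_keep: float = 0.30  # survival of CG dinucleotides in background
    cgi_base_probs: tuple[float, ...] = (0.17, 0.33, 0.33, 0.17)
    cgi_g_after_c: float = 0.35
    # extra G-after-C probability inside TSS windows: real TSS regions are
    # locally CpG-enriched even without a full island; GC stays ~40 % so this
    # never creates a detectable island on its own
    tss_cpg_boost: float = 0.08
    # layout
    min_gap: int = 2200
    # coverage
    coverage_lambda: float = 30.0
    # true CpG levels
    background_cpg: dict[str, float] = field(
        default_factory=lambda: {"blood": 0.60, "brain": 0.68}
    )
    te_body_cpg: dict[str, float] = field(
        default_factory=lambda: {"blood": 0.65, "brain": 0.85}
    )
    gb_cpg_range: tuple[float, float] = (0.45, 0.75)  # increasing with length rank
    gb_noise_sd: float = 0.02
    tss_cpg_range: tuple[float, float] = (0.02, 0.40)
    promoter_cgi_level: float = 0.08
    intragenic_cgi_level: float = 0.35
    intergenic_cgi_level: float = 0.35
    diff_cgi_levels: tuple[float, float] = (0.15, 0.55)
    site_jitter_sd: float = 0.03
    # planted differential genes (fractions per direction)
    diff_tss_fraction: float = 0.02
    diff_gb_fraction: float = 0.025
    diff_tss_levels: tuple[float, float] = (0.05, 0.45)
    diff_gb_levels: tuple[float, float] = (0.45, 0.85)
    # non-CpG methylation (brain)
    p_meth_cac: float = 0.34
    p_meth_cag: float = 0.24
    p_meth_cpa_other: float = 0.045
    p_meth_cpt: float = 0.0435
    p_meth_cpc: float = 0.0045
    noncpg_meth_beta: tuple[float, float] = (2.0, 6.0)
    noncpg_base_level: float = 0.002
    blood_noncpg_level: float = 0.001
    te_body_noncpg_mult: float = 0.5
    te_flank_mult_range: tuple[float, float] = (0.3, 1.7)
    gene_noncpg_mult_range: tuple[float, float] = (0.4, 1.6)
    # expression
    expr_baseline_log2: float = 5.0
    expr_beta: float = 3.0
    expr_sigma: float = 0.45
    te_active_base: float = 0.55
    te_active_slope: float = 0.25
    te_fpkm_log2_mean: float = 3.0
    te_fpkm_log2_sd: float = 1.0

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


def te_only_config(n_tes: int = 2000, seed_lengths=(500, 3000)) -> SyntheticConfig:
    """Config for the TE-expression coupling experiment: TEs with generous
    spacing so 2 kb flanks never touch a neighbour; no genes or islands."""
    mean_len = sum(seed_lengths) / 2
    chrom_len = int(n_tes * (mean_len + 4700) + 10_000)
    return SyntheticConfig(
        chrom_lengths={"te_chr": chrom_len},
        n_genes=0,
        n_tes=n_tes,
        te_length_range=seed_lengths,
        te_short_fraction=0.0,
        promoter_cgi_fraction=0.0,
        n_intragenic_cgis=0,
        n_intergenic_cgis=0,
        n_diff_cgis=0,
        min_gap=4500,
    )


@dataclass
class SyntheticDataset:
    """Generated study: genome, annotations, true level maps, truth tables."""

    config: SyntheticConfig
    seed: int
    genome: dict[str, str]
    transcripts: list[GeneModel]
    genes: list[GeneModel]
    tes: list[TERecord]
    cgi_truth: pd.DataFrame
    gene_truth: pd.DataFrame
    te_truth: pd.DataFrame
    cpg_level: dict[str, dict[str, np.ndarray]]  # tissue -> chrom -> per-bp level
    noncpg_mult: dict[str, np.ndarray]  # chrom -> per-bp propensity multiplier
    _contexts: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def contexts(self, chrom: str) -> pd.DataFrame:
        if chrom not in self._contexts:
            self._contexts[chrom] = mio.classify_contexts_array(self.genome[chrom])
        return self._contexts[chrom]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(k) for k in key])


# ---------------------------------------------------------------------------
# sequence
# ---------------------------------------------------------------------------

def _background_sequence(length: int, cfg: SyntheticConfig, rng) -> np.ndarray:
    seq = rng.choice(_BASES, size=length, p=cfg.bg_base_probs)
    cg = np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))
    kill = cg[rng.random(len(cg)) >= cfg.bg_cpg_keep]
    seq[kill + 1] = rng.choice(np.frombuffer(b"AT", dtype=np.uint8), size=len(kill))
    return seq


def _island_sequence(length: int, cfg: SyntheticConfig, rng) -> np.ndarray:
    seq = rng.choice(_BASES, size=length, p=cfg.cgi_base_probs)
    cpos = np.flatnonzero(seq[:-1] == ord("C"))
    force = cpos[rng.random(len(cpos)) < cfg.cgi_g_after_c]
    seq[force + 1] = ord("G")
    return seq


# ---------------------------------------------------------------------------
# structure
# ---------------------------------------------------------------------------

def _take_bases(exons: list[tuple[int, int]], strand: str, n: int, skip: int
                ) -> list[tuple[int, int]]:
    """Genomic intervals of transcript bases [skip, skip+n) in 5'→3' order."""
    walk = exons if strand == "+" else [(s, e) for s, e in reversed(exons)]
    out, off = [], 0
    for s, e in walk:
        L = e - s
        lo, hi = max(skip, off), min(skip + n, off + L)
        if hi > lo:
            if strand == "+":
                out.append((s + (lo - off), s + (hi - off)))
            else:
                out.append((e - (hi - off), e - (lo - off)))
        off += L
    return sorted(out)


def _make_transcripts(gid, chrom, strand, start, length, cfg, rng) -> list[GeneModel]:
    k = int(rng.integers(*cfg.exon_count_range, endpoint=True))
    k = max(2, min(k, length // 400))
    min_ex, min_in = 30, 50
    exon_total = max(k * min_ex, int(0.45 * length))
    intron_total = length - exon_total
    exon_lens = rng.multinomial(exon_total - k * min_ex, np.full(k, 1 / k)) + min_ex
    intron_lens = rng.multinomial(intron_total - (k - 1) * min_in, np.full(k - 1, 1 / (k - 1))) + min_in
    exons, cur = [], start
    for i in range(k):
        exons.append((cur, cur + int(exon_lens[i])))
        cur += int(exon_lens[i])
        if i < k - 1:
            cur += int(intron_lens[i])
    end = exons[-1][1]
    tl = sum(e - s for s, e in exons)
    u5, u3 = min(150, tl // 10), min(300, tl // 5)
    utr5 = _take_bases(exons, strand, u5, 0)
    cds = _take_bases(exons, strand, tl - u5 - u3, u5)
    utr3 = _take_bases(exons, strand, u3, tl - u3)
    t1 = GeneModel(f"{gid}.t1", chrom, strand, start, end, exons, cds, utr5, utr3)
    out = [t1]
    if k > 2 and rng.random() < cfg.isoform_fraction:
        # identical boundaries, one internal exon skipped
        drop = int(rng.integers(1, k - 1))
        kept = [iv for i, iv in enumerate(exons) if i != drop]
        clip = lambda ivs: [
            (max(s, lo), min(e, hi))
            for s, e in ivs
            for lo, hi in kept
            if min(e, hi) > max(s, lo)
        ]
        out.append(
            GeneModel(f"{gid}.t2", chrom, strand, start, end, kept,
                      clip(cds), clip(utr5), clip(utr3))
        )
    return out


def _place_elements(cfg: SyntheticConfig, lengths: list[int], rng
                    ) -> list[tuple[str, int]]:
    """Assign each element a (chrom, start) with gaps >= min_gap, spreading
    leftover space randomly.  Raises on infeasible packing."""
    chroms = list(cfg.chrom_lengths)
    order = rng.permutation(len(lengths))
    # round-robin by cumulative length to balance chromosomes
    per_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    loads = {c: 0 for c in chroms}
    for idx in order:
        c = min(chroms, key=lambda x: loads[x] / cfg.chrom_lengths[x])
        per_chrom[c].append(int(idx))
        loads[c] += lengths[idx] + cfg.min_gap
    placements: list[tuple[str, int] | None] = [None] * len(lengths)
    for c in chroms:
        idxs = per_chrom[c]
        total = sum(lengths[i] for i in idxs)
        slack = cfg.chrom_lengths[c] - total - (len(idxs) + 1) * cfg.min_gap
        if slack < 0:
            raise ValueError(
                f"infeasible packing: {len(idxs)} elements ({total} bp) do not fit "
                f"in {c} ({cfg.chrom_lengths[c]} bp) with {cfg.min_gap} bp gaps"
            )
        extra = rng.multinomial(slack, np.full(len(idxs) + 1, 1 / (len(idxs) + 1)))
        cur = 0
        for j, i in enumerate(idxs):
            cur += cfg.min_gap + int(extra[j])
            placements[i] = (c, cur)
            cur += lengths[i]
    return placements  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_genome(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Build the genome, annotations, truth tables and true level maps."""
    cfg = config or SyntheticConfig()
    rng = _rng(seed, _T_STRUCT)

    # ---- element lengths -------------------------------------------------
    glo, ghi = cfg.gene_length_range
    gene_lengths = np.exp(rng.uniform(np.log(glo), np.log(ghi), cfg.n_genes)).astype(int)
    tlo, thi = cfg.te_length_range
    te_lengths = rng.integers(tlo, thi, cfg.n_tes, endpoint=True)
    n_short = int(round(cfg.te_short_fraction * cfg.n_tes))
    if n_short:
        te_lengths[:n_short] = rng.integers(300, 499, n_short, endpoint=True)
    ilo, ihi = cfg.cgi_length_range
    n_inter = cfg.n_intergenic_cgis
    if cfg.n_diff_cgis > n_inter:
        raise ValueError("n_diff_cgis cannot exceed n_intergenic_cgis")
    inter_cgi_lengths = rng.integers(ilo, ihi, n_inter, endpoint=True)

    lengths = list(gene_lengths) + list(te_lengths) + list(inter_cgi_lengths)
    kinds = ["gene"] * cfg.n_genes + ["te"] * cfg.n_tes + ["cgi"] * n_inter
    placements = _place_elements(cfg, lengths, rng)

    # ---- genes -----------------------------------------------------------
    transcripts: list[GeneModel] = []
    for i in range(cfg.n_genes):
        chrom, start = placements[i]
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.extend(
            _make_transcripts(f"g{i:04d}", chrom, strand, start, int(gene_lengths[i]), cfg, rng)
        )
    genes = merge_transcripts(transcripts)
    genes_by_id = {g.id: g for g in genes}
    gene_ids = sorted(genes_by_id)

    # ---- planted gene sets ----------------------------------------------
    order = [gene_ids[i] for i in rng.permutation(len(gene_ids))]
    n_prom = int(round(cfg.promoter_cgi_fraction * cfg.n_genes))
    promoter_cgi_genes = order[:n_prom]
    pool = order[n_prom:]
    n_tss = math.floor(cfg.diff_tss_fraction * cfg.n_genes)
    n_gb = math.floor(cfg.diff_gb_fraction * cfg.n_genes)
    need = 2 * n_tss + 2 * n_gb
    if len(pool) < need:
        raise ValueError("not enough genes outside promoter-CGI set for planting")
    tss_hyper, tss_hypo = pool[:n_tss], pool[n_tss : 2 * n_tss]
    gb_hyper = pool[2 * n_tss : 2 * n_tss + n_gb]
    gb_hypo = pool[2 * n_tss + n_gb : need]
    # intragenic hosts: any unplanted gene long enough that a centered island
    # stays > 500 bp clear of the promoter window (genes with a promoter CGI
    # may also carry an intragenic island)
    hosts = [g for g in pool[need:] + promoter_cgi_genes if genes_by_id[g].length >= 2000]
    if len(hosts) < cfg.n_intragenic_cgis:
        raise ValueError("not enough long unplanted genes to host intragenic islands")
    intragenic_hosts = hosts[: cfg.n_intragenic_cgis]

    # ---- per-gene truth --------------------------------------------------
    lr = {g: r for r, g in enumerate(sorted(gene_ids, key=lambda g: (genes_by_id[g].length, g)))}
    denom = max(1, len(gene_ids) - 1)
    tss_lo, tss_hi = cfg.tss_cpg_range
    gb_lo, gb_hi = cfg.gb_cpg_range
    rows = []
    for gid in gene_ids:
        g = genes_by_id[gid]
        gb_blood = gb_lo + (gb_hi - gb_lo) * lr[gid] / denom + rng.normal(0, cfg.gb_noise_sd)
        gb_blood = float(np.clip(gb_blood, 0.02, 0.95))
        gb = {"blood": gb_blood, "brain": gb_blood}
        tss_level = float(rng.uniform(tss_lo, tss_hi))
        tss = {"blood": tss_level, "brain": tss_level}
        planted = "none"
        if gid in promoter_cgi_genes:
            tss = {"blood": cfg.promoter_cgi_level, "brain": cfg.promoter_cgi_level}
        if gid in tss_hyper:
            planted, tss = "tss_hyper_brain", {"blood": cfg.diff_tss_levels[0], "brain": cfg.diff_tss_levels[1]}
        elif gid in tss_hypo:
            planted, tss = "tss_hypo_brain", {"blood": cfg.diff_tss_levels[1], "brain": cfg.diff_tss_levels[0]}
        elif gid in gb_hyper:
            planted, gb = "gb_hyper_brain", {"blood": cfg.diff_gb_levels[0], "brain": cfg.diff_gb_levels[1]}
        elif gid in gb_hypo:
            planted, gb = "gb_hypo_brain", {"blood": cfg.diff_gb_levels[1], "brain": cfg.diff_gb_levels[0]}
        rows.append(
            {
                "id": gid, "chrom": g.chrom, "strand": g.strand, "start": g.start,
                "end": g.end, "length": g.length, "planted": planted,
                "tss_level_blood": tss["blood"], "tss_level_brain": tss["brain"],
                "gb_level_blood": gb["blood"], "gb_level_brain": gb["brain"],
                "noncpg_mult": float(rng.uniform(*cfg.gene_noncpg_mult_range)),
                "has_promoter_cgi": gid in promoter_cgi_genes,
            }
        )
    gene_truth = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["id", "chrom", "strand", "start", "end", "length", "planted",
                 "tss_level_blood", "tss_level_brain", "gb_level_blood",
                 "gb_level_brain", "noncpg_mult", "has_promoter_cgi"])

    # ---- TEs -------------------------------------------------------------
    te_rows, tes = [], []
    fam_probs = {"SINE": 0.2, "LINE": 0.5, "LTR": 0.3}
    for j in range(cfg.n_tes):
        chrom, start = placements[cfg.n_genes + j]
        L = int(te_lengths[j])
        fam = rng.choice(list(fam_probs), p=list(fam_probs.values()))
        strand = "+" if rng.random() < 0.5 else "-"
        te = TERecord(f"{chrom}:{start}-{start + L}", str(fam), chrom, start, start + L, strand)
        tes.append(te)
        te_rows.append(
            {
                "id": te.id, "family": te.family, "chrom": chrom, "start": start,
                "end": start + L, "strand": strand, "length": L,
                "flank_mult": float(rng.uniform(*cfg.te_flank_mult_range)),
            }
        )
    te_truth = pd.DataFrame(te_rows) if te_rows else pd.DataFrame(
        columns=["id", "family", "chrom", "start", "end", "strand", "length", "flank_mult"])

    # ---- CpG islands -----------------------------------------------------
    cgi_rows = []
    for gid in promoter_cgi_genes:
        g = genes_by_id[gid]
        L = int(rng.integers(*cfg.cgi_length_range, endpoint=True))
        s = max(0, g.tss - L // 2)
        lv = cfg.promoter_cgi_level
        cgi_rows.append({"chrom": g.chrom, "start": s, "end": s + L, "cls": "promoter",
                         "level_blood": lv, "level_brain": lv, "differential": False,
                         "direction": ""})
    for gid in intragenic_hosts:
        g = genes_by_id[gid]
        L = int(rng.integers(*cfg.cgi_length_range, endpoint=True))
        L = min(L, g.length - 1200)  # keep the island out of the promoter window
        mid = (g.start + g.end) // 2
        lv = cfg.intragenic_cgi_level
        cgi_rows.append({"chrom": g.chrom, "start": mid - L // 2, "end": mid - L // 2 + L,
                         "cls": "intragenic", "level_blood": lv, "level_brain": lv,
                         "differential": False, "direction": ""})
    diff_pick = set(rng.permutation(n_inter)[: cfg.n_diff_cgis].tolist())
    for j in range(n_inter):
        chrom, start = placements[cfg.n_genes + cfg.n_tes + j]
        L = int(inter_cgi_lengths[j])
        if j in diff_pick:
            lo, hi = cfg.diff_cgi_levels
            if rng.random() < 0.5:
                lv_blood, lv_brain, direction = lo, hi, "hyper_in_brain"
            else:
                lv_blood, lv_brain, direction = hi, lo, "hypo_in_brain"
            cgi_rows.append({"chrom": chrom, "start": start, "end": start + L,
                             "cls": "intergenic", "level_blood": lv_blood,
                             "level_brain": lv_brain, "differential": True,
                             "direction": direction})
        else:
            lv = cfg.intergenic_cgi_level
            cgi_rows.append({"chrom": chrom, "start": start, "end": start + L,
                             "cls": "intergenic", "level_blood": lv, "level_brain": lv,
                             "differential": False, "direction": ""})
    cgi_truth = pd.DataFrame(cgi_rows) if cgi_rows else pd.DataFrame(
        columns=["chrom", "start", "end", "cls", "level_blood", "level_brain",
                 "differential", "direction"])
    if len(cgi_truth):
        cgi_truth.insert(0, "id", [
            f"{r.chrom}:{r.start}-{r.end}" for r in cgi_truth.itertuples()
        ])

    # ---- sequence --------------------------------------------------------
    genome: dict[str, str] = {}
    for ci, (chrom, L) in enumerate(cfg.chrom_lengths.items()):
        srng = _rng(seed, _T_SEQ, ci)
        seq = _background_sequence(L, cfg, srng)
        for r in gene_truth.itertuples():  # mild CpG enrichment at every TSS
            if r.chrom != chrom or cfg.tss_cpg_boost <= 0:
                continue
            g = genes_by_id[r.id]
            t = g.tss
            s, e = (t - 300, t + 51) if g.strand == "+" else (t - 50, t + 301)
            s, e = max(0, s), min(L, e)
            cpos = s + np.flatnonzero(seq[s : e - 1] == ord("C"))
            force = cpos[srng.random(len(cpos)) < cfg.tss_cpg_boost]
            seq[force + 1] = ord("G")
        for r in cgi_truth.itertuples():
            if r.chrom == chrom:
                seq[r.start : r.end] = _island_sequence(r.end - r.start, cfg, srng)
        genome[chrom] = seq.tobytes().decode("ascii")

    # ---- true level maps -------------------------------------------------
    cpg_level = {t: {} for t in ("blood", "brain")}
    noncpg_mult: dict[str, np.ndarray] = {}
    for chrom, L in cfg.chrom_lengths.items():
        for tissue in ("blood", "brain"):
            m = np.full(L, cfg.background_cpg[tissue], np.float32)
            for r in gene_truth.itertuples():
                if r.chrom == chrom:
                    m[r.start : r.end] = getattr(r, f"gb_level_{tissue}")
            for r in te_truth.itertuples():
                if r.chrom == chrom:
                    m[r.start : r.end] = cfg.te_body_cpg[tissue]
            for r in gene_truth.itertuples():  # TSS window paints over GB/flank
                if r.chrom != chrom:
                    continue
                g = genes_by_id[r.id]
                t = g.tss
                s, e = (t - 300, t + 51) if g.strand == "+" else (t - 50, t + 301)
                m[max(0, s) : min(L, e)] = getattr(r, f"tss_level_{tissue}")
            for r in cgi_truth.itertuples():
                if r.chrom == chrom:
                    m[r.start : r.end] = getattr(r, f"level_{tissue}")
            cpg_level[tissue][chrom] = m
        mm = np.ones(L, np.float32)
        for r in gene_truth.itertuples():
            if r.chrom == chrom:
                mm[r.start : r.end] = r.noncpg_mult
        for r in te_truth.itertuples():
            if r.chrom != chrom:
                continue
            mm[max(0, r.start - cfg.te_flank) : r.start] = r.flank_mult
            mm[r.end : min(L, r.end + cfg.te_flank)] = r.flank_mult
            # body propensity shares the per-TE factor, scaled down: TEs are
            # non-CpG hypomethylated relative to their flanks
            mm[r.start : r.end] = cfg.te_body_noncpg_mult * r.flank_mult
        noncpg_mult[chrom] = mm

    return SyntheticDataset(
        config=cfg, seed=seed, genome=genome, transcripts=transcripts, genes=genes,
        tes=tes, cgi_truth=cgi_truth, gene_truth=gene_truth, te_truth=te_truth,
        cpg_level=cpg_level, noncpg_mult=noncpg_mult,
    )


# ---------------------------------------------------------------------------
# methylome / expression / annotation emission
# ---------------------------------------------------------------------------

def true_site_levels(data: SyntheticDataset, tissue: str, chrom: str) -> pd.DataFrame:
    """Per-cytosine true methylation levels for one tissue and chromosome."""
    cfg = data.config
    ctx = data.contexts(chrom)
    pos = ctx["pos"].to_numpy()
    level = np.empty(len(ctx), float)

    is_cpg = (ctx["context"] == "CpG").to_numpy()
    jit = _rng(data.seed, _T_JITTER, _chrom_index(data, chrom)).normal(
        0.0, cfg.site_jitter_sd, int(is_cpg.sum())
    )
    level[is_cpg] = np.clip(
        data.cpg_level[tissue][chrom][pos[is_cpg]].astype(float) + jit, 0.005, 0.995
    )

    non = ~is_cpg
    if tissue == "brain":
        trinuc = ctx["trinuc"].to_numpy()[non]
        second = ((trinuc >> 8) & 0xFF).astype(np.uint8)
        third = (trinuc & 0xFF).astype(np.uint8)
        p = np.select(
            [
                (second == ord("A")) & (third == ord("C")),
                (second == ord("A")) & (third == ord("G")),
                second == ord("A"),
                second == ord("T"),
            ],
            [cfg.p_meth_cac, cfg.p_meth_cag, cfg.p_meth_cpa_other, cfg.p_meth_cpt],
            default=cfg.p_meth_cpc,
        )
        p = np.clip(p * data.noncpg_mult[chrom][pos[non]].astype(float), 0.0, 0.8)
        nrng = _rng(data.seed, _T_NONCPG, _chrom_index(data, chrom))
        meth = nrng.random(len(p)) < p
        lv = np.full(len(p), cfg.noncpg_base_level)
        lv[meth] = nrng.beta(*cfg.noncpg_meth_beta, int(meth.sum()))
        level[non] = lv
    else:
        level[non] = cfg.blood_noncpg_level

    out = ctx[["pos", "strand", "context", "dinuc"]].copy()
    out["level"] = level
    return out


def _chrom_index(data: SyntheticDataset, chrom: str) -> int:
    return list(data.genome).index(chrom)


def simulate_methylome(
    data: SyntheticDataset,
    tissue: str,
    coverage_lambda: float | None = None,
    read_seed: int = 0,
) -> pd.DataFrame:
    """Draw a sequencing experiment: Poisson coverage, binomial methylated reads.

    ``read_seed`` shifts only the read-sampling stream, emulating an
    independent library (e.g. a second platform) over the same true levels.
    Sites with zero coverage are omitted.
    """
    cfg = data.config
    lam = cfg.coverage_lambda if coverage_lambda is None else coverage_lambda
    tix = {"blood": 0, "brain": 1}[tissue]
    frames = []
    for chrom in data.genome:
        truth = true_site_levels(data, tissue, chrom)
        rrng = _rng(data.seed, _T_READS, tix, _chrom_index(data, chrom), read_seed)
        n_total = rrng.poisson(lam, len(truth))
        keep = n_total > 0
        if not keep.any():
            continue
        n_tot = n_total[keep]
        n_meth = rrng.binomial(n_tot, truth["level"].to_numpy()[keep])
        sub = truth.loc[keep, ["pos", "strand", "context", "dinuc"]].copy()
        sub.insert(0, "chrom", chrom)
        sub["n_meth"] = n_meth
        sub["n_total"] = n_tot
        frames.append(sub)
    if not frames:
        return finalize_sites(
            pd.DataFrame(columns=["chrom", "pos", "strand", "context", "dinuc",
                                  "n_meth", "n_total"])
        )
    return finalize_sites(pd.concat(frames, ignore_index=True))


def simulate_expression(data: SyntheticDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene and TE FPKM tables coupled to the planted methylation truth.

    Gene log2 FPKM decreases in the brain TSS level (slope ``expr_beta``);
    TE expression is zero-inflated with activity probability decreasing in the
    flank non-CpG propensity.  Also stores FPKM on the TE records/truth.
    """
    cfg = data.config
    rng = _rng(data.seed, _T_EXPR)
    g = data.gene_truth
    log2 = (
        cfg.expr_baseline_log2
        - cfg.expr_beta * g["tss_level_brain"].to_numpy()
        + rng.normal(0, cfg.expr_sigma, len(g))
    )
    gene_fpkm = pd.DataFrame({"id": g["id"], "fpkm": np.power(2.0, log2)})

    t = data.te_truth
    p_active = np.clip(
        cfg.te_active_base - cfg.te_active_slope * (t["flank_mult"].to_numpy() - 1.0),
        0.05, 0.95,
    )
    active = rng.random(len(t)) < p_active
    fpkm = np.where(
        active, np.power(2.0, rng.normal(cfg.te_fpkm_log2_mean, cfg.te_fpkm_log2_sd, len(t))), 0.0
    )
    te_fpkm = pd.DataFrame({"id": t["id"], "fpkm": fpkm})
    data.te_truth = t.assign(p_active=p_active, fpkm=fpkm)
    for te, f in zip(data.tes, fpkm):
        te.fpkm = float(f)
    return gene_fpkm, te_fpkm


def simulate_annotation(data: SyntheticDataset, n_terms: int = 30,
                        terms_per_gene: tuple[int, int] = (1, 5)) -> pd.DataFrame:
    """Gene→term annotation with one term per planted gene set.

    Every gene gets 1-5 random generic terms; in addition each planted set
    (tss/gb × hyper/hypo) shares a dedicated term, so over-representation of
    those terms in the recovered extreme sets is the expected signal.
    """
    rng = _rng(data.seed, _T_ANNOT)
    rows = []
    ids = data.gene_truth["id"].tolist()
    for gid in ids:
        k = int(rng.integers(*terms_per_gene, endpoint=True))
        for term in rng.choice(n_terms, size=k, replace=False):
            rows.append((gid, f"T{int(term):04d}"))
    for planted, sub in data.gene_truth.groupby("planted"):
        if planted == "none":
            continue
        for gid in sub["id"]:
            rows.append((gid, f"SET_{planted.upper()}"))
    return pd.DataFrame(rows, columns=["gene", "term"]).drop_duplicates(ignore_index=True)


# ---------------------------------------------------------------------------
# on-disk emission
# ---------------------------------------------------------------------------

def write_dataset(data: SyntheticDataset, outdir, tissues=("blood", "brain")) -> dict[str, Path]:
    """Emit the study as the standard file formats plus truth tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    mio.write_fasta(data.genome, out / "genome.fa")
    paths["genome"] = out / "genome.fa"
    mio.write_gff3_genes(data.transcripts, out / "genes.gff3")
    paths["genes"] = out / "genes.gff3"
    mio.write_te_bed(data.tes, out / "tes.bed")
    paths["tes"] = out / "tes.bed"
    gene_fpkm, te_fpkm = simulate_expression(data)
    mio.write_fpkm_table(gene_fpkm, out / "gene_fpkm.tsv")
    mio.write_fpkm_table(te_fpkm, out / "te_fpkm.tsv")
    paths["gene_fpkm"], paths["te_fpkm"] = out / "gene_fpkm.tsv", out / "te_fpkm.tsv"
    annot = simulate_annotation(data)
    annot.to_csv(out / "annotation.tsv", sep="\t", header=False, index=False)
    paths["annotation"] = out / "annotation.tsv"
    for tissue in tissues:
        sites = simulate_methylome(data, tissue)
        mio.write_cgmap(sites, out / f"{tissue}.cgmap")
        paths[f"{tissue}_cgmap"] = out / f"{tissue}.cgmap"
    for name in ("gene_truth", "te_truth", "cgi_truth"):
        getattr(data, name).to_csv(out / f"{name}.tsv", sep="\t", index=False,
                                   float_format="%.6g")
        paths[name] = out / f"{name}.tsv"
    return paths
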