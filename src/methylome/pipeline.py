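"""End-to-end orchestration: files in, report tables out.

``run_pipeline`` executes the full downstream analysis over two tissues —
site summaries, gene-feature methylation, fold-change differential genes,
CpG islands, non-CpG motifs, TE methylation/expression, optional gene-set
enrichment — and writes deterministic TSV reports plus a JSON run manifest.
Tissue A is the tissue of interest (brain-like: non-CpG methylation,
expression data); tissue B is the comparison tissue.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cgi as mcgi
from . import differential as mdiff
from . import io as mio
from . import motifs as mmot
from . import te as mte
from .enrichment import enrichment_table, hypergeom_enrich, read_annotation
from .features import (
    derive_features,
    length_decile_means,
    merge_transcripts,
    summarize_region,
    window_profile,
)
from .sites import SiteIndex
from .util import pct

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


@dataclass
class PipelineConfig:
    fasta: str
    gff: str
    cgmap_a: str
    cgmap_b: str
    tissue_a: str = "brain"
    tissue_b: str = "blood"
    te_bed: str | None = None
    gene_fpkm: str | None = None
    te_fpkm: str | None = None
    annotation: str | None = None
    outdir: str = "methylome_out"
    min_depth: int = 10
    methylated_threshold: float = 0.10
    min_sites: int = 3
    tail_fraction: float = 0.025
    te_min_len: int = 500
    q_cutoff: float = 0.05
    fold_change_eps: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if not (1 <= self.min_depth and 0 < self.methylated_threshold < 1
                and self.min_sites >= 1 and 0 < self.tail_fraction < 0.5
                and 0 < self.q_cutoff <= 1 and self.fold_change_eps > 0):
            raise ValueError("pipeline thresholds outside documented ranges")
        for attr in ("fasta", "gff", "cgmap_a", "cgmap_b", "te_bed",
                     "gene_fpkm", "te_fpkm", "annotation"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


@_stage("site_summary")
def site_summary_table(sites_by_tissue: dict[str, pd.DataFrame], threshold: float
                       ) -> pd.DataFrame:
    """Per context × tissue: covered sites, mean level over sites shared by
    both tissues (%), methylated site count and methylation density (%)."""
    tissues = list(sites_by_tissue)
    keyed = {
        t: s.set_index(["chrom", "pos", "strand"]) for t, s in sites_by_tissue.items()
    }
    shared = keyed[tissues[0]].index.intersection(keyed[tissues[1]].index)
    rows = []
    for ctx in ("CpG", "CHG", "CHH"):
        for t in tissues:
            df = keyed[t]
            sub = df[df["context"] == ctx]
            sh = sub.loc[sub.index.intersection(shared), "level"]
            n_meth = int((sub["level"] > threshold).sum())
            rows.append(
                {
                    "context": ctx,
                    "tissue": t,
                    "covered_sites": len(sub),
                    "mean_level_shared_pct": round(float(sh.mean() * 100), 2) if len(sh) else math.nan,
                    "methylated_sites": n_meth,
                    "density_pct": pct(n_meth, len(sub), 2) if len(sub) else math.nan,
                }
            )
    return pd.DataFrame(rows)


@_stage("feature_methylation")
def feature_summaries(
    genes, chrom_lengths, indexes: dict[str, SiteIndex], cfg: PipelineConfig
) -> pd.DataFrame:
    rows = []
    for g in genes:
        regions = derive_features(g, chrom_lengths[g.chrom])
        for kind in ("TSS", "5UTR", "CDS", "intron", "3UTR", "GB", "TTS"):
            region = regions[kind]
            for context in ("CpG", "nonCpG"):
                for tissue, index in indexes.items():
                    s = summarize_region(region, index, context, cfg.min_sites,
                                         cfg.methylated_threshold)
                    rows.append(
                        {"gene": g.id, "feature": kind, "context": context,
                         "tissue": tissue, "n_sites": s.n_sites,
                         "mean_level": s.mean_level, "density": s.density,
                         "defined": s.defined}
                    )
    return pd.DataFrame(rows)


def _summary_maps(table: pd.DataFrame, feature: str, context: str):
    """Rebuild {tissue: {gene: summary-like}} from the feature table."""
    from .features import RegionMethylationSummary

    out: dict[str, dict] = {}
    sub = table[(table["feature"] == feature) & (table["context"] == context)]
    for r in sub.itertuples():
        out.setdefault(r.tissue, {})[r.gene] = RegionMethylationSummary(
            r.gene, feature, context, r.n_sites, r.mean_level, r.density, r.defined
        )
    return out


@_stage("metagene")
def metagene_table(genes, chrom_lengths, indexes, context="CpG") -> pd.DataFrame:
    """Mean window profile over genes for GB and 10 kb flanks, per tissue."""
    rows = []
    for tissue, index in indexes.items():
        acc: dict[str, list] = {"upstream10k": [], "GB": [], "downstream10k": []}
        for g in genes:
            regions = derive_features(g, chrom_lengths[g.chrom])
            for kind in acc:
                prof = window_profile(regions[kind], index, context)
                if prof.defined:
                    acc[kind].append([w[2] for w in prof.windows])
        for kind, mat in acc.items():
            if not mat:
                continue
            means = np.nanmean(np.asarray(mat, float), axis=0)
            for i, mval in enumerate(means):
                rows.append({"tissue": tissue, "region": kind, "window": i,
                             "mean_level": float(mval)})
    return pd.DataFrame(rows)


@_stage("differential_genes")
def differential_report(feature_table, gene_fpkm: pd.DataFrame | None, cfg: PipelineConfig):
    """Fold-change tables, extreme sets and a Table-3-shaped expression report."""
    fpkm = gene_fpkm.set_index("id")["fpkm"] if gene_fpkm is not None else None
    diff_frames, table3_rows, extreme_sets = [], [], {}
    for feature in ("TSS", "GB", "TTS"):
        maps = _summary_maps(feature_table, feature, "CpG")
        res = mdiff.differential_table(
            maps[cfg.tissue_a], maps[cfg.tissue_b], feature,
            eps=cfg.fold_change_eps,
        )
        hyper, hypo = mdiff.select_extremes(res, cfg.tail_fraction)
        extreme_sets[f"{feature}_hyper_{cfg.tissue_a}"] = hyper
        extreme_sets[f"{feature}_hypo_{cfg.tissue_a}"] = hypo
        diff_frames.append(pd.DataFrame(
            [{"gene": r.gene_id, "feature": feature,
              f"level_{cfg.tissue_a}": r.level_a, f"level_{cfg.tissue_b}": r.level_b,
              "log2_fc": r.fold_change, "category": r.category} for r in res]
        ))
        row = {"feature": feature,
               "covered": sum(1 for r in res if r.category != "filtered"),
               "tail_size": len(hyper)}
        if fpkm is not None:
            hypo_f = fpkm.reindex(hypo).dropna()
            hyper_f = fpkm.reindex(hyper).dropna()
            if len(hypo_f) >= 2 and len(hyper_f) >= 2:
                t, p = mdiff.expression_ttest(hypo_f, hyper_f)
                row.update(
                    {f"hypo_{cfg.tissue_a}_fpkm_mean": float(hypo_f.mean()),
                     f"hypo_{cfg.tissue_a}_fpkm_median": float(hypo_f.median()),
                     f"hyper_{cfg.tissue_a}_fpkm_mean": float(hyper_f.mean()),
                     f"hyper_{cfg.tissue_a}_fpkm_median": float(hyper_f.median()),
                     "t_stat": t, "t_p": p}
                )
        table3_rows.append(row)
    return pd.concat(diff_frames, ignore_index=True), pd.DataFrame(table3_rows), extreme_sets


@_stage("cgi")
def cgi_report(genome, genes, indexes, cfg: PipelineConfig):
    islands = mcgi.predict_cgis_genome(genome)
    for isl in islands:
        mcgi.classify_cgi(isl, genes)
    results = mcgi.test_cgis(
        islands, indexes[cfg.tissue_a], indexes[cfg.tissue_b],
        min_sites=cfg.min_sites, q_cutoff=cfg.q_cutoff,
    )
    tests = pd.DataFrame(
        [{"island": r.island.id, "class": r.island.location,
          "n_sites_a": r.n_sites_a, "n_sites_b": r.n_sites_b,
          "meth_a": r.counts[0][0], "unmeth_a": r.counts[0][1],
          "meth_b": r.counts[1][0], "unmeth_b": r.counts[1][1],
          f"level_{cfg.tissue_a}": r.level_a, f"level_{cfg.tissue_b}": r.level_b,
          "p": r.p, "q": r.q, "direction": r.direction, "significant": r.significant}
         for r in results]
    )
    bed = pd.DataFrame(
        [{"chrom": i.chrom, "start": i.start, "end": i.end, "name": i.location,
          "obs_exp": round(i.obs_exp, 3), "gc_pct": round(i.gc_pct, 2)}
         for i in islands]
    )
    summary = mcgi.cgi_summary(islands, results)
    return islands, results, bed, tests, summary


@_stage("te")
def te_report(tes, indexes, chrom_lengths, te_fpkm, cfg: PipelineConfig):
    kept = mte.filter_tes(tes, cfg.te_min_len)
    if te_fpkm is not None:
        fmap = te_fpkm.set_index("id")["fpkm"]
        for t in kept:
            if t.id in fmap.index:
                t.fpkm = float(fmap[t.id])
    profile_rows, corr_rows = [], []
    for context in ("CpG", "nonCpG"):
        for tissue, index in indexes.items():
            acc = {r: [] for r in mte.TE_REGIONS}
            for t in kept:
                for region, prof in mte.te_profiles(
                    t, index, chrom_lengths[t.chrom], context
                ).items():
                    if prof.defined:
                        acc[region].append([w[2] for w in prof.windows])
            for region, mat in acc.items():
                if not mat:
                    continue
                means = np.nanmean(np.asarray(mat, float), axis=0)
                for i, mval in enumerate(means):
                    profile_rows.append(
                        {"context": context, "tissue": tissue, "region": region,
                         "window": i, "mean_level": float(mval)}
                    )
        if te_fpkm is not None and any(t.fpkm is not None for t in kept):
            means = mte.te_region_means(kept, indexes[cfg.tissue_a], chrom_lengths,
                                        context, cfg.min_sites)
            for c in mte.te_expression_correlation(means, context):
                corr_rows.append(dataclasses.asdict(c))
    return pd.DataFrame(profile_rows), pd.DataFrame(corr_rows)


def run_pipeline(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every stage and write the report bundle under ``cfg.outdir``."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            k: getattr(cfg, k)
            for k in ("min_depth", "methylated_threshold", "min_sites",
                      "tail_fraction", "te_min_len", "q_cutoff", "fold_change_eps")
        },
        "dropped": {},
    }

    log.info("reading inputs")
    genome = mio.read_fasta(cfg.fasta)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    transcripts = mio.read_gff3_genes(cfg.gff)
    genes = merge_transcripts(transcripts)
    manifest["n_transcripts"], manifest["n_genes"] = len(transcripts), len(genes)
    sites = {}
    for tissue, path in ((cfg.tissue_a, cfg.cgmap_a), (cfg.tissue_b, cfg.cgmap_b)):
        raw = mio.read_cgmap(path)
        sites[tissue] = mio.filter_depth(raw, cfg.min_depth)
        manifest["dropped"][f"{tissue}_below_depth"] = len(raw) - len(sites[tissue])
        manifest[f"{tissue}_covered_sites"] = len(sites[tissue])
    indexes = {t: SiteIndex(s) for t, s in sites.items()}

    results: dict[str, pd.DataFrame] = {}

    results["table1"] = site_summary_table(sites, cfg.methylated_threshold)
    dinuc = mmot.dinucleotide_summary(sites[cfg.tissue_a], cfg.methylated_threshold)
    results["table2"] = dinuc
    results["context_proportions"] = pd.concat(
        [mmot.context_proportions(sites[t], cfg.methylated_threshold).assign(tissue=t)
         for t in sites],
        ignore_index=True,
    )

    log.info("gene features")
    feats = feature_summaries(genes, chrom_lengths, indexes, cfg)
    results["feature_summaries"] = feats
    results["metagene"] = metagene_table(genes, chrom_lengths, indexes)
    gb_maps = _summary_maps(feats, "GB", "CpG")
    results["length_deciles"] = length_decile_means(
        genes, gb_maps[cfg.tissue_b]
    ).assign(tissue=cfg.tissue_b)

    log.info("differential genes")
    gene_fpkm = mio.read_fpkm_table(cfg.gene_fpkm) if cfg.gene_fpkm else None
    diff_table, table3, extreme_sets = differential_report(feats, gene_fpkm, cfg)
    results["differential_genes"] = diff_table
    results["table3"] = table3

    noncpg_rows = []
    for feature in ("TSS", "GB", "TTS"):
        maps = _summary_maps(feats, feature, "nonCpG")
        defined = {g: s for g, s in maps[cfg.tissue_a].items() if s.defined}
        if len(defined) >= 40:
            for pg in mdiff.noncpg_percentile_groups(defined, feature):
                noncpg_rows.append({"gene": pg.gene_id, "feature": feature,
                                    "group": pg.group})
    results["noncpg_groups"] = pd.DataFrame(noncpg_rows)

    log.info("CpG islands")
    islands, cgi_results, bed, tests, table4 = cgi_report(genome, genes, indexes, cfg)
    results["cgi_bed"], results["cgi_tests"], results["table4"] = bed, tests, table4

    log.info("non-CpG motifs")
    for context in ("CHH", "CHG"):
        mm = mmot.motif_matrix(genome, sites[cfg.tissue_a], context,
                               methylated_threshold=cfg.methylated_threshold)
        frame = mm.counts.copy()
        frame.insert(0, "position", mm.positions)
        frame["IC_bits"] = mm.information_content.to_numpy()
        results[f"motif_{context}"] = frame.reset_index(drop=True)

    if cfg.te_bed:
        log.info("transposable elements")
        tes = mio.read_te_bed_or_gff(cfg.te_bed)
        te_fpkm = mio.read_fpkm_table(cfg.te_fpkm) if cfg.te_fpkm else None
        manifest["n_tes"] = len(tes)
        profiles, corrs = te_report(tes, indexes, chrom_lengths, te_fpkm, cfg)
        results["te_profiles"] = profiles
        if len(corrs):
            results["te_correlations"] = corrs

    if cfg.annotation and extreme_sets:
        log.info("enrichment")
        ann = read_annotation(cfg.annotation)
        enr_frames = []
        for name, study in sorted(extreme_sets.items()):
            if not study:
                continue
            res = hypergeom_enrich(study, ann, universe_ids={g.id for g in genes})
            enr_frames.append(enrichment_table(res).assign(study=name))
        if enr_frames:
            results["enrichment"] = pd.concat(enr_frames, ignore_index=True)

    for name, set_genes in extreme_sets.items():
        (out / f"genes_{name}.txt").write_text("".join(f"{g}\n" for g in set_genes))
    for name, df in results.items():
        _write(df, out / f"{name}.tsv")
    manifest["outputs"] = sorted(results)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results
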