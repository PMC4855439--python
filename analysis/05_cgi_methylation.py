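#!/usr/bin/env python
"""CpG islands: prediction, genomic classification, differential methylation.

Predicts islands from the genome sequence (100 bp windows, O/E >= 0.6,
GC >= 50 %, >= 200 bp), classifies them against the gene annotation
(promoter > intragenic > intergenic), Fisher-tests pooled CpG read counts
between tissues with Bonferroni correction, and writes the island BED, the
per-island test table and the class-wise summary.
"""

from pathlib import Path

import pandas as pd

import methylome.cgi as mcgi
import methylome.io as mio
from methylome.features import merge_transcripts
from methylome.sites import SiteIndex

ROOT = Path(__file__).resolve().parents[1]
IN, OUT = ROOT / "results" / "synthetic", ROOT / "results" / "tables"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = mio.read_fasta(IN / "genome.fa")
    genes = merge_transcripts(mio.read_gff3_genes(IN / "genes.gff3"))
    indexes = {
        t: SiteIndex(mio.filter_depth(mio.read_cgmap(IN / f"{t}.cgmap"), 10))
        for t in ("blood", "brain")
    }

    islands = mcgi.predict_cgis_genome(genome)
    for isl in islands:
        mcgi.classify_cgi(isl, genes)
    results = mcgi.test_cgis(islands, indexes["brain"], indexes["blood"])

    pd.DataFrame(
        [{"chrom": i.chrom, "start": i.start, "end": i.end, "name": i.location,
          "obs_exp": round(i.obs_exp, 3), "gc_pct": round(i.gc_pct, 2)}
         for i in islands]
    ).to_csv(OUT / "cgi.bed", sep="\t", index=False, header=False)
    pd.DataFrame(
        [{"island": r.island.id, "class": r.island.location,
          "meth_brain": r.counts[0][0], "unmeth_brain": r.counts[0][1],
          "meth_blood": r.counts[1][0], "unmeth_blood": r.counts[1][1],
          "level_brain": round(r.level_a, 4), "level_blood": round(r.level_b, 4),
          "p": r.p, "q": r.q, "direction": r.direction, "significant": r.significant}
         for r in results]
    ).to_csv(OUT / "cgi_tests.tsv", sep="\t", index=False)

    summary = mcgi.cgi_summary(islands, results)
    summary.to_csv(OUT / "cgi_summary.tsv", sep="\t", index=False)
    print(f"{len(islands)} islands predicted, {len(results)} tested "
          "(>= 3 covered CpGs in both tissues)")
    for r in summary.itertuples():
        print(f"  {r._1:<11} n={r.n_cgis:<4} ({r.pct_of_total:>5} %) "
              f"differential {r.n_differential} ({r.pct_differential} %), "
              f"hyper/hypo in brain {r.n_hyper_in_a}/{r.n_hypo_in_a}")


if __name__ == "__main__":
    main()
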