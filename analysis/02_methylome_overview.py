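#!/usr/bin/env python
"""Genome-wide methylation landscape of the two tissues.

Reads the study bundle from results/synthetic/ and writes, under
results/tables/: the per-context methylation summary (covered sites,
shared-site mean levels, methylated counts, densities), the relative
proportion of methylated Cs per context, the non-CpG dinucleotide summary of
the brain-like tissue and the CHG/CHH sequence-context matrices with
per-position information content.
"""

from pathlib import Path

import methylome.io as mio
import methylome.motifs as mmot
from methylome.pipeline import site_summary_table

ROOT = Path(__file__).resolve().parents[1]
IN, OUT = ROOT / "results" / "synthetic", ROOT / "results" / "tables"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = mio.read_fasta(IN / "genome.fa")
    sites = {
        t: mio.filter_depth(mio.read_cgmap(IN / f"{t}.cgmap"), 10)
        for t in ("blood", "brain")
    }

    table1 = site_summary_table(sites, 0.10)
    table1.to_csv(OUT / "site_summary.tsv", sep="\t", index=False)
    t1 = table1.set_index(["context", "tissue"])
    print("CpG mean level (shared sites): "
          f"blood {t1.loc[('CpG', 'blood'), 'mean_level_shared_pct']} %, "
          f"brain {t1.loc[('CpG', 'brain'), 'mean_level_shared_pct']} %")
    print("CHH methylation density: "
          f"blood {t1.loc[('CHH', 'blood'), 'density_pct']} %, "
          f"brain {t1.loc[('CHH', 'brain'), 'density_pct']} % "
          "(non-CpG methylation is brain-specific)")

    props = [
        mmot.context_proportions(s).assign(tissue=t) for t, s in sites.items()
    ]
    import pandas as pd

    pd.concat(props, ignore_index=True).to_csv(
        OUT / "context_proportions.tsv", sep="\t", index=False
    )

    dinuc = mmot.dinucleotide_summary(sites["brain"])
    dinuc.to_csv(OUT / "dinucleotide_summary.tsv", sep="\t", index=False)
    shares = mmot.dinucleotide_shares(dinuc)
    print(f"brain methylated non-CpG sites: CpA share {shares['CpA_share_pct']:.0f} % "
          f"(CHG {shares['CpA_share_CHG_pct']:.0f} %, CHH {shares['CpA_share_CHH_pct']:.0f} %)")

    for ctx in ("CHH", "CHG"):
        mm = mmot.motif_matrix(genome, sites["brain"], ctx)
        frame = mm.counts.copy()
        frame.insert(0, "position", mm.positions)
        frame["IC_bits"] = mm.information_content.to_numpy()
        frame.to_csv(OUT / f"motif_{ctx}.tsv", sep="\t", index=False)
        print(f"{ctx} motif consensus (−3..+5): {mm.consensus()} "
              f"({mm.n_sites:,} methylated sites)")


if __name__ == "__main__":
    main()
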