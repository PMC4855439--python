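#!/usr/bin/env python
"""Generate the synthetic two-tissue (brain/blood-like) methylome study.

Emits the full input bundle the downstream analyses consume — genome FASTA,
gene GFF3, TE BED, per-tissue CGmap methylation calls, gene/TE FPKM tables,
a gene→term annotation — plus the generator's ground-truth tables, under
results/synthetic/.
"""

from pathlib import Path

from methylome.simulate import SyntheticConfig, generate_genome, write_dataset

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    cfg = SyntheticConfig()
    data = generate_genome(cfg, seed=SEED)
    paths = write_dataset(data, OUT)
    print(f"seed {SEED}; genome {sum(map(len, data.genome.values())):,} bp "
          f"({len(data.genome)} chromosomes)")
    print(f"{len(data.genes)} genes ({len(data.transcripts)} transcripts), "
          f"{len(data.tes)} TEs, {len(data.cgi_truth)} CpG islands "
          f"({int(data.cgi_truth['differential'].sum())} planted differential)")
    planted = data.gene_truth["planted"].value_counts()
    print("planted gene sets:", dict(planted[planted.index != "none"]))
    for name, p in sorted(paths.items()):
        print(f"  {name}: {p.relative_to(OUT.parent.parent)}")


if __name__ == "__main__":
    main()
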