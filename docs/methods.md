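# Methods

## Data model and conventions

All genomic coordinates are 0-based half-open on the + strand; GFF3 input
(1-based closed) is converted on read and the conversion is an exact
bijection. A *site* is one cytosine on one strand; its context is defined by
the two bases 3' of the C on its own strand (CpG; CHG when the second base is
G; CHH otherwise), and its dinucleotide class (CpA/CpT/CpC/CpG) by the
immediate 3' base. Cytosines within 2 bp of a sequence 3' end, or whose
trinucleotide window contains an ambiguity code, have no defined context and
are excluded from context-dependent analyses (counts are logged). CGmap
input carries a redundant level column; the read counts are authoritative
and the level is recomputed after a ±0.01 consistency check. All analyses
use sites covered by ≥ 10 reads.

Region methylation is the **unweighted mean of per-site levels** of the
requested context within the region's interval set, with sites from both
strands included (CpG sites are palindromic and the study's regions are
strand-derived, not strand-filtered). Pooling read counts instead would
weight sites by coverage; pooled counts are used only where a count-based
test requires them (the island Fisher test). A region with fewer than
`min_sites` (default 3) covered sites is *undefined* and drops out of
downstream ranking. Methylated-site thresholds are strict (> 10 %)
everywhere.

## Gene features and profiles

The TSS window spans 300 bp upstream to 50 bp downstream of the annotated
start (both offsets inclusive → 351 bp; clamped at chromosome edges, never
failing) and the TTS window 50 bp upstream to 200 bp downstream (251 bp),
mirrored on the − strand. The gene body (GB) is the full annotated span;
introns are GB minus the exon union; transcripts with identical
(chrom, strand, TSS, TTS) are merged into one gene with the exon union
(equality is exact — "similar boundaries" is read as identity).

Metagene profiles cut a contiguous region into 40 sliding windows of 5 % of
the region length stepped every 2.5 % (10 windows of 20 % stepped 10 % for
TEs). This layout overshoots the region by half a window; the final window
is clamped to the region end. Windows are reported 5'→3' in gene/TE
orientation. One consequence of the clamp is that a − strand profile is not
exactly the reverse of the + strand profile of the same interval; the
invariant that does hold (and is tested) is mirror symmetry: the − strand
profile equals the + strand profile after mirroring coordinates.

Gene-length deciles sort genes by GB length into 10 equal-count bins
(remainder to the last bins, ties stable by gene id) and average the
per-gene mean levels within each bin.

## Differential genes

Per feature (TSS, GB, TTS) and per gene, the fold change is
`log2((ℓ_brain + ε)/(ℓ_blood + ε))` with pseudocount ε = 0.01 (configurable);
the published procedure states no formula, and the log form makes the two
tails symmetric. Features are ranked only when both tissue summaries are
defined and `ℓ_a + ℓ_b > 0.10`. Each tail holds `floor(0.025 · n_ranked)`
genes, ties broken by gene id, which guarantees disjoint deterministic sets.
Expression contrasts between the tails use a pooled-variance two-sample
t-test on untransformed FPKM (df = n_a + n_b − 2); degenerate zero-variance
inputs return p = 1 (equal means) or p = 0 (unequal, flagged by an infinite
statistic). Non-CpG percentile groups sort genes ascending by non-CpG mean
level into 40 equal-count groups, remainder to the highest groups.

## CpG islands

A 100 bp window sliding by 1 bp passes when O/E = N_CpG·w/(N_C·N_G) ≥ 0.6
(undefined when N_C·N_G = 0 ⇒ fail) and GC ≥ 50 %; maximal runs of
consecutive passing start positions merge into a candidate from the first
window's start to the last window's end, and candidates ≥ 200 bp are
reported with O/E and GC recomputed over the island. N_CpG counts CG
dinucleotides fully inside the window. No smoothing is applied: the
detector is defined by this rule and verified against an O(n·w) brute-force
oracle. Note that passing windows overhang a dense block by up to w − 1 bp
on each side, so a block shorter than the minimum length can still seed a
reportable candidate; this is a property of the window rule itself.

Islands are classified with precedence promoter ≻ intragenic ≻ intergenic
(promoter window: TSS −2000/+500 bp, strand-aware, inclusive), so the
classes partition the island set. Differential testing pools methylated and
unmethylated read counts over the island's covered CpG sites per tissue into
a 2×2 table — read counts rather than site counts use all information — and
computes the two-sided Fisher exact p by summing hypergeometric point
probabilities ≤ the observed table's (small relative tolerance for float
ties). Only islands with ≥ 3 covered CpG sites in *both* tissues are tested,
and the Bonferroni factor m is the number of islands actually tested;
q = min(1, p·m), significant at q ≤ 0.05.

## Non-CpG motifs and enrichment

Motif matrices accumulate base counts from 3 bp upstream to 5 bp downstream
of each methylated (level > 10 %) site of one context class, on the site's
own strand (− strand windows reverse-complemented); windows leaving the
sequence or containing N are skipped and logged. Information content per
column is `2 + Σ_b p_b log2 p_b` bits with 0·log 0 = 0 and no small-sample
correction (a correction is a rendering-time choice, not applied here).

Term enrichment is the one-sided hypergeometric upper tail
`P[X ≥ k]` for k study genes among K term carriers in a universe of N, with
Benjamini–Hochberg FDR across terms; the universe defaults to all genes
carrying at least one annotation. Terms with no carriers in the universe are
skipped.

## Synthetic study: what it emulates

The generator emits the study conditions the analyses assume, with one
master seed fixing every byte (independent named RNG streams for structure,
sequence, site jitter, non-CpG state, reads per tissue, expression,
annotation).

**Genome and annotation.** Two 1.5 Mb chromosomes by default. (The layout
packs 200 genes of 1.5–8 kb, 300 TEs of 0.5–3 kb and 260 CpG-island blocks
with ≥ 2.2 kb gaps — chosen so that no element can fall into a neighbouring
gene's promoter window — which does not fit in less than ~3 Mb.) Background
sequence is CpG-depleted (O/E ≈ 0.3, GC 40 %); island blocks are CpG-rich
(O/E ≈ 1.4, GC ≈ 66 %); every TSS window gets a mild CpG enrichment
(O/E ≈ 0.65 but GC ≈ 40 %, below the island GC threshold), reflecting real
promoters and guaranteeing enough CpG sites for TSS summaries. About 10 % of
genes are emitted as two identical-boundary isoforms to exercise transcript
merging; 5 % of TEs are shorter than the 500 bp analysis cutoff.

**CpG levels.** Per-bp true-level maps per tissue: background 0.60 (blood) /
0.68 (brain), TE bodies 0.65/0.85, gene bodies rising from 0.45 to 0.75 with
gene-length rank (identical across tissues), per-gene TSS levels uniform on
0.02–0.40 (shared), promoter islands 0.08, intragenic/intergenic islands
0.35. A per-site jitter (σ = 0.03), shared between tissues, adds within-
region variation without breaking any between-tissue null. Planted
differential sets (Δ = 0.4): TSS genes (blood/brain 0.05 vs 0.45, 2 % of
genes per direction), GB genes (0.45 vs 0.85, 2.5 % per direction) and 50
intergenic islands (0.15 vs 0.55, half per direction). Planted genes are
kept free of islands so the planted effect is what the analysis sees;
differential islands are intergenic only, so they cannot leak into the
gene-level contrast.

**Non-CpG.** Brain sites are methylated (level ~ Beta(2,6), else 0.002) with
trinucleotide-dependent probability CAC 0.34 > CAG 0.24 > other CpA 0.045 >
CpT 0.0435 ≫ CpC 0.0045 — calibrated analytically so the realized
per-dinucleotide mean levels land on CpA ≈ 3.4 %, CpT ≈ 1.2 %, CpC ≈ 0.3 %
and CpA carries ~75 % of methylated non-CpG sites with a CAC-shaped CHH
motif. Blood non-CpG is a flat 0.001. Gene spans carry a per-gene
multiplier (0.4–1.6) to give the percentile grouping real variation; TE
flanks carry a per-TE multiplier f ~ U(0.3, 1.7) and TE bodies 0.5·f
(bodies hypomethylated relative to flanks, as observed in the real data).

**Reads.** Coverage is Poisson(30) per site and tissue (zero-coverage sites
omitted), methylated reads Binomial(coverage, true level). A `read_seed`
parameter redraws only the read stream, emulating an independent library of
the same tissue for the cross-platform concordance check (depth 20 there).

**Expression.** Gene log2 FPKM = 5 − 3·(brain TSS level) + N(0, 0.45); the
noise level was set by a power calculation so that at the 400-gene study the
recovered extreme TSS sets separate in expression at p < 0.01 with margin
(β = 3 and Δ = 0.4 give a ~2.3× FPKM ratio). TE FPKM is zero-inflated:
active with probability clip(0.55 − 0.25·(f − 1)), active FPKM lognormal.
The slope 0.25 was calibrated by simulation so the measured upstream
non-CpG Spearman ρ at n = 2000 TEs sits at the −0.2 target (measurement
noise in flank means attenuates the raw coupling).

**What it does not emulate** — and hence what passing tests do not show
about real data: replicate individuals and biological variance between them
(the design has one methylome per tissue, like the study it mirrors),
bisulfite conversion failure and sequencing error, mappability structure,
TE families with distinct methylation behaviour, GO-term semantics (the
annotation is random apart from one planted term per gene set), and any
genome-scale numbers that depend on the real genome's composition.

## Problem sizes and determinism

The default study is 3 Mb / ~1.16 M sites per tissue; the differential-gene
recovery experiment uses 400 genes on 4.4 Mb; the TE coupling experiment
uses 2000 TEs on ~13 Mb (brain only). These sizes keep every planted effect
comfortably above its sampling noise (binomial noise on a ≥ 30-site region
mean at 30× is ~0.02, an order of magnitude below the planted Δ = 0.4)
while the full suite and the acceptance script each run in minutes on one
CPU. Reports are written with fixed float formatting and a content-only
manifest, so a repeated run with the same seed is byte-identical; the
pipeline is single-threaded and order-deterministic throughout.
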