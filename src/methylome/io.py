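"""Readers and writers for the formats the pipeline touches.

Supported formats: CGmap methylation-call tables (8-column TSV), FASTA genomes,
GFF3 gene annotation, BED4+/GFF transposable-element annotation and two-column
FPKM expression tables.  Everything is normalized to the internal model:
0-based half-open coordinates on the + strand, levels recomputed from read
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import GeneModel, TERecord, finalize_sites

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Malformed input file; message names the file and line."""


@dataclass
class ContextCall:
    """Result of classifying one cytosine; ``context is None`` for sites that
    are undefined (too close to the 3' end on their own strand, or ambiguous
    bases in the trinucleotide window)."""

    context: str | None
    dinuc: str | None
    reason: str | None = None


# ---------------------------------------------------------------------------
# CGmap methylation calls
# ---------------------------------------------------------------------------

_CGMAP_CONTEXT = {"CG": "CpG", "CHG": "CHG", "CHH": "CHH"}
_CGMAP_DINUC = {"CA": "CpA", "CC": "CpC", "CG": "CpG", "CT": "CpT"}


def read_cgmap(path) -> pd.DataFrame:
    """Read a CGmap-style call file into the canonical site table.

    Columns: chrom, nucleotide (C for + strand, G for −), 1-based position,
    context (CG/CHG/CHH), dinucleotide (e.g. CA), level, methylated reads,
    total reads.  The level column is redundant with the counts and is only
    checked for consistency (|level − m/t| ≤ 0.01), then recomputed.
    """
    try:
        raw = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "nuc", "pos1", "ctx", "dinuc", "level", "n_meth", "n_total"],
            dtype={"chrom": str, "nuc": str, "ctx": str, "dinuc": str},
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc

    def bad(mask: pd.Series, why: str):
        if mask.any():
            line = int(np.flatnonzero(mask.to_numpy())[0]) + 1
            raise ParseError(f"{path}, line {line}: {why}")

    bad(raw[["chrom", "nuc", "pos1", "ctx", "dinuc", "level", "n_meth", "n_total"]].isna().any(axis=1),
        "expected 8 tab-separated columns")
    bad(~raw["nuc"].isin(["C", "G"]), "nucleotide must be C or G")
    bad(~raw["ctx"].isin(_CGMAP_CONTEXT), "unknown context token")
    bad(~raw["dinuc"].isin(_CGMAP_DINUC), "unknown dinucleotide token")
    bad(raw["pos1"] < 1, "position must be >= 1")
    bad((raw["n_total"] < 1) | (raw["n_meth"] < 0) | (raw["n_meth"] > raw["n_total"]),
        "inconsistent read counts (need 0 <= n_meth <= n_total, n_total >= 1)")
    bad((raw["level"] - raw["n_meth"] / raw["n_total"]).abs() > 0.01 + 1e-12,
        "level column disagrees with counts by more than 0.01")
    ctx = raw["ctx"].map(_CGMAP_CONTEXT)
    dinuc = raw["dinuc"].map(_CGMAP_DINUC)
    bad((ctx == "CpG") != (dinuc == "CpG"), "dinucleotide CG must pair with context CG")

    df = pd.DataFrame(
        {
            "chrom": raw["chrom"],
            "pos": raw["pos1"].astype(np.int64) - 1,
            "strand": np.where(raw["nuc"] == "C", "+", "-"),
            "context": ctx,
            "dinuc": dinuc,
            "n_meth": raw["n_meth"],
            "n_total": raw["n_total"],
        }
    )
    return finalize_sites(df)


def write_cgmap(sites: pd.DataFrame, path) -> None:
    """Write a site table back to CGmap layout (inverse of :func:`read_cgmap`)."""
    out = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "nuc": np.where(sites["strand"] == "+", "C", "G"),
            "pos1": sites["pos"] + 1,
            "ctx": sites["context"].map({"CpG": "CG", "CHG": "CHG", "CHH": "CHH"}),
            "dinuc": sites["dinuc"].map({v: k for k, v in _CGMAP_DINUC.items()}),
            "level": (sites["n_meth"] / sites["n_total"]).round(6),
            "n_meth": sites["n_meth"],
            "n_total": sites["n_total"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def filter_depth(sites: pd.DataFrame, min_depth: int = 10) -> pd.DataFrame:
    """Keep sites covered by at least ``min_depth`` reads (order preserved)."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    return sites[sites["n_total"] >= min_depth].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Sequence context classification
# ---------------------------------------------------------------------------

def classify_context(genome: dict[str, str], chrom: str, pos: int, strand: str) -> ContextCall:
    """Classify the cytosine at ``(chrom, pos, strand)``.

    Reads the two bases 3' of the C on its own strand: next base G gives CpG,
    otherwise a G two bases away gives CHG, else CHH; the dinucleotide class is
    Cp{next base}.  Sites within 2 bp of the 3' sequence end are flagged
    ``edge``; an N in the trinucleotide window flags ``ambiguous``.
    """
    seq = genome[chrom]
    base = seq[pos]
    if strand == "+":
        if base != "C":
            raise ValueError(f"{chrom}:{pos}(+) is {base}, not C")
        if pos > len(seq) - 3:
            return ContextCall(None, None, "edge")
        n1, n2 = seq[pos + 1], seq[pos + 2]
    elif strand == "-":
        if base != "G":  # a − strand C appears as G on the reference
            raise ValueError(f"{chrom}:{pos}(-) is {base}, not C")
        if pos < 2:
            return ContextCall(None, None, "edge")
        n1 = seq[pos - 1].translate(_COMPLEMENT)
        n2 = seq[pos - 2].translate(_COMPLEMENT)
    else:
        raise ValueError(f"bad strand {strand!r}")
    if "N" in (base, n1, n2):
        return ContextCall(None, None, "ambiguous")
    if n1 == "G":
        return ContextCall("CpG", "CpG")
    context = "CHG" if n2 == "G" else "CHH"
    return ContextCall(context, f"Cp{n1}", None)


def classify_contexts_array(seq: str) -> pd.DataFrame:
    """Vectorized context classification of every usable cytosine in ``seq``.

    Returns a frame with columns pos, strand, context, dinuc, trinuc (the three
    bases 5'→3' from the C on its own strand).  Edge and N-window sites are
    dropped, matching the scalar :func:`classify_context` flags.
    """
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    comp = np.zeros(256, np.uint8)
    for x, y in zip(b"ACGTN", b"TGCAN"):
        comp[x] = y
    frames = []
    for strand in "+-":
        if strand == "+":
            idx = np.flatnonzero(a[:-2] == ord("C"))  # pos <= L-3
            n1, n2 = a[idx + 1], a[idx + 2]
        else:
            idx = np.flatnonzero(a[2:] == ord("G")) + 2  # pos >= 2
            n1, n2 = comp[a[idx - 1]], comp[a[idx - 2]]
        ok = (n1 != ord("N")) & (n2 != ord("N"))
        idx, n1, n2 = idx[ok], n1[ok], n2[ok]
        is_cpg = n1 == ord("G")
        context = pd.Categorical.from_codes(
            np.where(is_cpg, 0, np.where(n2 == ord("G"), 1, 2)),
            categories=["CpG", "CHG", "CHH"],
        )
        dinuc = pd.Categorical.from_codes(
            np.searchsorted(np.frombuffer(b"ACGT", dtype=np.uint8), n1),
            categories=["CpA", "CpC", "CpG", "CpT"],
        )
        trinuc = (
            np.full(len(idx), ord("C"), np.uint32) * 0x10000 + n1.astype(np.uint32) * 0x100 + n2
        )
        frames.append(
            pd.DataFrame(
                {"pos": idx, "strand": strand, "context": context, "dinuc": dinuc,
                 "trinuc": trinuc}
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)


def decode_trinuc(code: int) -> str:
    return "".join(chr((code >> s) & 0xFF) for s in (16, 8, 0))


# ---------------------------------------------------------------------------
# Genome / annotation / expression
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Load a FASTA genome as ``{name: uppercase sequence}``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff3_genes(path) -> list[GeneModel]:
    """Read gene models from GFF3, one :class:`GeneModel` per transcript.

    GFF3 1-based closed intervals become 0-based half-open.  Genes without
    mRNA children are treated as single transcripts; unknown feature types are
    ignored (count logged).  Duplicate gene IDs or missing ID/Parent raise.
    """
    known = {"gene", "mRNA", "transcript", "exon", "CDS", "five_prime_UTR", "three_prime_UTR"}
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="error", keep_order=True
        )
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc

    skipped = sum(1 for f in db.all_features() if f.featuretype not in known)
    if skipped:
        log.info("%s: ignored %d records of unknown feature types", path, skipped)

    models: list[GeneModel] = []
    seen: set[str] = set()
    for gene in db.features_of_type("gene"):
        if gene.id in seen:
            raise ParseError(f"{path}: duplicate gene ID {gene.id}")
        seen.add(gene.id)
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript"), level=1))
        if not transcripts:
            transcripts = [gene]
        for t in transcripts:
            def ivs(ftype):
                return [
                    (f.start - 1, f.end)
                    for f in db.children(t, featuretype=ftype, level=1)
                ]
            exons = ivs("exon") or [(t.start - 1, t.end)]
            models.append(
                GeneModel(
                    id=t.id,
                    chrom=gene.seqid,
                    strand=gene.strand,
                    start=t.start - 1,
                    end=t.end,
                    exons=exons,
                    cds=ivs("CDS"),
                    utr5=ivs("five_prime_UTR"),
                    utr3=ivs("three_prime_UTR"),
                )
            )
    return models


def write_gff3_genes(models: list[GeneModel], path) -> None:
    """Write transcripts as gene/mRNA/exon/CDS/UTR GFF3 (inverse of the reader
    for single-transcript genes; transcript ids of form ``<gene>.t<N>`` are
    grouped under one gene)."""
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        gid = m.id.split(".t")[0]
        by_gene.setdefault(gid, []).append(m)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, ts in by_gene.items():
            start = min(t.start for t in ts)
            end = max(t.end for t in ts)
            t0 = ts[0]
            fh.write(
                f"{t0.chrom}\tsynthetic\tgene\t{start + 1}\t{end}\t.\t{t0.strand}\t.\tID={gid}\n"
            )
            for ti, t in enumerate(ts, 1):
                tid = t.id if t.id != gid else f"{gid}.t{ti}"
                fh.write(
                    f"{t.chrom}\tsynthetic\tmRNA\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t"
                    f"ID={tid};Parent={gid}\n"
                )
                for kind, ivs in (
                    ("exon", t.exons),
                    ("CDS", t.cds),
                    ("five_prime_UTR", t.utr5),
                    ("three_prime_UTR", t.utr3),
                ):
                    for j, (s, e) in enumerate(ivs, 1):
                        fh.write(
                            f"{t.chrom}\tsynthetic\t{kind}\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                            f"ID={tid}.{kind}{j};Parent={tid}\n"
                        )


def read_te_bed_or_gff(path) -> list[TERecord]:
    """Read TE annotation from BED4+ (name column ``FAMILY/subtype``) or GFF3."""
    path = str(path)
    tes: list[TERecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                if len(f) >= 9 and f[3].isdigit():  # GFF3
                    attrs = dict(
                        kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                    )
                    tes.append(
                        TERecord(
                            id=attrs.get("ID", f"te{lineno}"),
                            family=attrs.get("family", f[2]).split("/")[0],
                            chrom=f[0],
                            start=int(f[3]) - 1,
                            end=int(f[4]),
                            strand=f[6] if f[6] in "+-" else "+",
                        )
                    )
                else:  # BED
                    name = f[3] if len(f) > 3 else f"te{lineno}"
                    strand = f[5] if len(f) > 5 and f[5] in "+-" else "+"
                    tes.append(
                        TERecord(
                            id=f"{f[0]}:{f[1]}-{f[2]}",
                            family=name.split("/")[0],
                            chrom=f[0],
                            start=int(f[1]),
                            end=int(f[2]),
                            strand=strand,
                        )
                    )
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
    return tes


def write_te_bed(tes: list[TERecord], path) -> None:
    with open(path, "w") as fh:
        for t in tes:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.family}\t0\t{t.strand}\n")


def read_fpkm_table(path) -> pd.DataFrame:
    """Read a two-column expression table (header ``id<TAB>fpkm``)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["id", "fpkm"]:
        raise ParseError(f"{path}: expected header columns 'id' and 'fpkm'")
    if (df["fpkm"] < 0).any():
        raise ParseError(f"{path}: negative FPKM")
    return df[["id", "fpkm"]]


def write_fpkm_table(df: pd.DataFrame, path) -> None:
    df[["id", "fpkm"]].to_csv(path, sep="\t", index=False, float_format="%.6g")
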