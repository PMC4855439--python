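"""Core domain types for the methylome analyses.

Conventions used throughout the package:

* All genomic coordinates are 0-based, half-open, on the + strand of the
  reference.  Strand-relative arithmetic (TSS windows, motif flanks, window
  orientation) is localized in the functions that derive regions.
* A "site" is one cytosine on one strand.  Cytosine context is defined by the
  two bases 3' of the C on its own strand: CpG (next base G), CHG (next base
  not G, the one after G) or CHH (neither).  The dinucleotide class CpA / CpT /
  CpC / CpG records the immediate 3' base.
* Methylation level is methylated reads / total reads at the site (0-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTEXTS = ("CpG", "CHG", "CHH")
DINUCLEOTIDES = ("CpA", "CpC", "CpG", "CpT")

#: canonical column order of a site table
SITE_COLUMNS = ("chrom", "pos", "strand", "context", "dinuc", "n_meth", "n_total", "level")


@dataclass(frozen=True)
class MethSite:
    """One cytosine with bisulfite read counts.

    ``pos`` is the 0-based reference coordinate of the cytosine (for a − strand
    site this is the position of the G on the + reference strand).
    """

    chrom: str
    pos: int
    strand: str
    context: str
    dinuc: str
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total < 1 or self.n_meth < 0 or self.n_meth > self.n_total:
            raise ValueError(
                f"inconsistent counts at {self.chrom}:{self.pos}: "
                f"{self.n_meth}/{self.n_total}"
            )
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.dinuc not in DINUCLEOTIDES:
            raise ValueError(f"unknown dinucleotide {self.dinuc!r}")
        if (self.context == "CpG") != (self.dinuc == "CpG"):
            raise ValueError("dinucleotide is CpG iff context is CpG")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def level(self) -> float:
        return self.n_meth / self.n_total


def sites_frame(records) -> pd.DataFrame:
    """Build the canonical site table from an iterable of tuples/``MethSite``.

    The table (a pandas DataFrame with columns :data:`SITE_COLUMNS`) is the
    collection type used by every analysis; ``level`` is always recomputed from
    the counts.
    """
    rows = []
    for r in records:
        if isinstance(r, MethSite):
            rows.append((r.chrom, r.pos, r.strand, r.context, r.dinuc, r.n_meth, r.n_total))
        else:
            rows.append(tuple(r[:7]))
    df = pd.DataFrame(rows, columns=SITE_COLUMNS[:7])
    return finalize_sites(df)


def finalize_sites(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize dtypes and recompute ``level`` on a raw site table."""
    df = df.copy()
    df["pos"] = df["pos"].astype(np.int64)
    df["n_meth"] = df["n_meth"].astype(np.int64)
    df["n_total"] = df["n_total"].astype(np.int64)
    for col, cats in (("strand", ("+", "-")), ("context", CONTEXTS), ("dinuc", DINUCLEOTIDES)):
        df[col] = pd.Categorical(df[col], categories=cats)
    df["level"] = df["n_meth"] / df["n_total"]
    return df[list(SITE_COLUMNS)]


@dataclass
class GeneModel:
    """A gene (or a single transcript before merging) with derived intervals.

    All sub-intervals are half-open on + strand coordinates and lie within
    ``[start, end)``.  ``tss``/``tts`` are single coordinates: on the + strand
    the TSS is ``start`` and the TTS is ``end - 1``; mirrored on the − strand.
    """

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty gene span for {self.id}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand for {self.id}")
        self.exons = sorted(self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"exon outside gene span in {self.id}")
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping exons in {self.id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TERecord:
    """A transposable element annotation with optional expression."""

    id: str
    family: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    fpkm: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ExpressionRecord:
    id: str
    fpkm: float

    def __post_init__(self) -> None:
        if not (self.fpkm >= 0):
            raise ValueError(f"negative FPKM for {self.id}")
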