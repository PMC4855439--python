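"""Gene-set over-representation by the hypergeometric test.

Given a study list, a term→genes annotation and a gene universe, each term is
scored with the upper-tail hypergeometric probability of drawing at least the
observed number of annotated genes, then corrected across terms with the
Benjamini-Hochberg FDR.  This is the statistical core of a GO-style analysis,
deliberately decoupled from term assignment and DAG propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # study genes carrying the term
    n_study: int
    K: int  # universe genes carrying the term
    N: int  # universe size
    p: float
    q: float
    enriched: bool


def read_annotation(path) -> dict[str, set[str]]:
    """Two-column TSV (gene id, term id) -> term → gene set."""
    ann: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
    for gene, term in zip(df["gene"], df["term"]):
        ann.setdefault(term, set()).add(gene)
    return ann


def hypergeom_enrich(
    study_ids,
    annotation: dict[str, set[str]],
    universe_ids=None,
    q_cutoff: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided over-representation of every annotated term in the study set.

    The universe defaults to all genes carrying at least one annotation; the
    study set must be a subset of the universe.  p = P[X >= k] for X
    hypergeometric(N, K, n_study); q by Benjamini-Hochberg over the tested
    terms (terms with K = 0 are skipped).  Results are sorted by (q, p, term).
    """
    if universe_ids is None:
        universe = set().union(*annotation.values()) if annotation else set()
    else:
        universe = set(universe_ids)
    study = set(study_ids)
    if not study or not universe:
        raise ValueError("study and universe must be non-empty")
    if not study <= universe:
        raise ValueError("study set must be contained in the universe")
    N, n_study = len(universe), len(study)
    rows = []
    for term in sorted(annotation):
        term_genes = annotation[term] & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & study)
        p = float(hypergeom.sf(k - 1, N, K, n_study))
        rows.append((term, k, K, min(1.0, p)))
    if not rows:
        return []
    _, qs, _, _ = multipletests([r[3] for r in rows], method="fdr_bh")
    out = [
        EnrichmentResult(term, k, n_study, K, N, p, float(q), bool(q <= q_cutoff))
        for (term, k, K, p), q in zip(rows, qs)
    ]
    out.sort(key=lambda r: (r.q, r.p, r.term))
    return out


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"term": r.term, "k": r.k, "n_study": r.n_study, "K": r.K, "N": r.N,
             "p": r.p, "q": r.q, "enriched": r.enriched}
            for r in results
        ]
    )
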