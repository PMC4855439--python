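"""Indexed access to site tables for interval queries.

Analyses repeatedly ask "all CpG levels in these intervals"; a per-chromosome,
per-context sorted-position index answers that with binary search instead of
boolean masks over the whole table.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_CONTEXT_SETS = {
    "CpG": ("CpG",),
    "CHG": ("CHG",),
    "CHH": ("CHH",),
    "nonCpG": ("CHG", "CHH"),
}


class SiteIndex:
    """Read-only index over a canonical site table.

    Parameters
    ----------
    sites
        Site table (see :mod:`methylome.model`); depth filtering is the
        caller's responsibility.
    """

    def __init__(self, sites: pd.DataFrame):
        self._store: dict[tuple[str, str], dict[str, np.ndarray]] = {}
        for (chrom, context), sub in sites.groupby(["chrom", "context"], observed=True):
            sub = sub.sort_values("pos", kind="mergesort")
            self._store[(str(chrom), str(context))] = {
                "pos": sub["pos"].to_numpy(np.int64),
                "level": sub["level"].to_numpy(float),
                "n_meth": sub["n_meth"].to_numpy(np.int64),
                "n_total": sub["n_total"].to_numpy(np.int64),
            }

    def _blocks(self, chrom: str, context: str):
        try:
            names = _CONTEXT_SETS[context]
        except KeyError:
            raise ValueError(f"unknown context selector {context!r}") from None
        for name in names:
            block = self._store.get((chrom, name))
            if block is not None:
                yield block

    def select(
        self,
        chrom: str,
        intervals: Iterable[tuple[int, int]],
        context: str = "CpG",
        columns: Sequence[str] = ("pos", "level"),
    ) -> dict[str, np.ndarray]:
        """Gather site columns for all sites inside a disjoint interval set."""
        parts: dict[str, list[np.ndarray]] = {c: [] for c in columns}
        for block in self._blocks(chrom, context):
            pos = block["pos"]
            for s, e in intervals:
                lo, hi = np.searchsorted(pos, (s, e))
                if hi > lo:
                    for c in columns:
                        parts[c].append(block[c][lo:hi])
        return {
            c: (np.concatenate(v) if v else np.empty(0, dtype=float)) for c, v in parts.items()
        }

    def levels(self, chrom, intervals, context="CpG") -> np.ndarray:
        return self.select(chrom, intervals, context, columns=("level",))["level"]

    def pooled_counts(self, chrom, intervals, context="CpG") -> tuple[int, int, int]:
        """(n_sites, sum n_meth, sum n_total) over an interval set."""
        got = self.select(chrom, intervals, context, columns=("n_meth", "n_total"))
        return len(got["n_meth"]), int(got["n_meth"].sum()), int(got["n_total"].sum())
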