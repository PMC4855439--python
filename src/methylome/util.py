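"""Shared numeric helpers: exact percentage arithmetic and interval utilities."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(part: float, whole: float, ndigits: int = 1) -> float:
    """part/whole as a percentage, rounded half away from zero.

    Integer inputs are computed in exact decimal arithmetic so that printed
    report percentages are reproducible from the underlying counts.
    """
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty total")
    val = Decimal(part) * 100 / Decimal(whole)
    q = Decimal(1).scaleb(-ndigits)
    out = float(val.quantize(q, rounding=ROUND_HALF_UP))
    return out


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals into a sorted disjoint set."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(
    span: tuple[int, int], holes: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Half-open ``span`` minus a set of half-open ``holes``."""
    s0, e0 = span
    out = []
    cur = s0
    for hs, he in merge_intervals(holes):
        hs, he = max(hs, s0), min(he, e0)
        if he <= hs:
            continue
        if hs > cur:
            out.append((cur, hs))
        cur = max(cur, he)
    if cur < e0:
        out.append((cur, e0))
    return out


def total_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in intervals)
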