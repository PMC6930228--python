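"""Genomic interval arithmetic on 0-based half-open (chrom, start, end) triples.

All public functions return sorted, merged interval lists. BED files are
read and written headerless, tab-separated, three columns minimum.
"""

from __future__ import annotations

import os
from typing import Iterable, List, Tuple

Interval = Tuple[str, int, int]


class IntervalError(ValueError):
    """Malformed interval or BED record."""


def _validate(iv: Interval) -> Interval:
    chrom, start, end = iv
    if end <= start or start < 0:
        raise IntervalError(f"invalid interval {chrom}:{start}-{end}")
    return (str(chrom), int(start), int(end))


def merge(intervals: Iterable[Interval]) -> List[Interval]:
    """Union of intervals: sorted by (chrom, start), overlapping or abutting
    intervals on the same chromosome collapsed into one."""
    ivs = sorted(_validate(iv) for iv in intervals)
    out: List[Interval] = []
    for chrom, start, end in ivs:
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            out.append((chrom, start, end))
    return out


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Intersection of two interval sets (each merged first)."""
    a_m, b_m = merge(a), merge(b)
    out: List[Interval] = []
    i = j = 0
    # linear sweep over the two sorted merged lists
    while i < len(a_m) and j < len(b_m):
        ca, sa, ea = a_m[i]
        cb, sb, eb = b_m[j]
        if ca < cb:
            i += 1
            continue
        if cb < ca:
            j += 1
            continue
        lo, hi = max(sa, sb), min(ea, eb)
        if lo < hi:
            out.append((ca, lo, hi))
        if ea <= eb:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(end - start for _, start, end in merge(intervals))


def read_bed(path: str | os.PathLike) -> List[Interval]:
    """Read a headerless BED file; only the first three columns are used."""
    out: List[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise IntervalError(f"{path}:{lineno}: expected >=3 columns")
            try:
                iv = (fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise IntervalError(f"{path}:{lineno}: {exc}") from exc
            out.append(_validate(iv))
    return out


def write_bed(intervals: Iterable[Interval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
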