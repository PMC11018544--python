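"""Interval-set operations (reciprocal-overlap intersection) and the SV
size-class binning used to stratify rejection rates."""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Optional, Sequence

from intervaltree import IntervalTree

from .svio import SVCall

#: bin edges in bp; bins are lower-exclusive, upper-inclusive
SIZE_BIN_EDGES = (20, 100, 250, 500, 1000, 5000, 10000, 500000)

SIZE_BIN_LABELS = (
    ">20 to 100 bp",
    ">100 to 250 bp",
    ">250 to 500 bp",
    ">500 bp to 1 kb",
    ">1 to 5 kb",
    ">5 to 10 kb",
    ">10 to 500 kb",
    ">500 kb",
)


@dataclass(frozen=True)
class SizeBin:
    label: str
    lower: int                 # exclusive
    upper: Optional[int]       # inclusive; None = unbounded


SIZE_BINS = tuple(
    SizeBin(label, SIZE_BIN_EDGES[i],
            SIZE_BIN_EDGES[i + 1] if i + 1 < len(SIZE_BIN_EDGES) else None)
    for i, label in enumerate(SIZE_BIN_LABELS)
)


def size_bin(svlen: int) -> str:
    """Bin label for a length; lengths <= 20 bp are below the caller's
    discovery floor and rejected."""
    if svlen <= SIZE_BIN_EDGES[0]:
        raise ValueError(f"svlen {svlen} is at or below the >20 bp discovery floor")
    # bisect_left on edges gives the count of edges < svlen for exclusive
    # lower bounds; subtract 1 for the bin index
    return SIZE_BIN_LABELS[bisect_left(SIZE_BIN_EDGES, svlen) - 1]


def _interval(x):
    """(chrom, start, end) from an SVCall or a 3-tuple."""
    if isinstance(x, SVCall):
        return x.chrom, x.start, x.end
    chrom, start, end = x
    return chrom, int(start), int(end)


def reciprocal_overlap(a, b) -> tuple:
    """Overlap length as a fraction of each interval's length.

    Accepts SVCall objects or (chrom, start, end) tuples with half-open
    coordinates; returns (0.0, 0.0) for disjoint intervals or different
    chromosomes.  Zero-length intervals are rejected.
    """
    chrom_a, start_a, end_a = _interval(a)
    chrom_b, start_b, end_b = _interval(b)
    if end_a <= start_a or end_b <= start_b:
        raise ValueError("intervals must have end > start")
    if chrom_a != chrom_b:
        return 0.0, 0.0
    overlap = min(end_a, end_b) - max(start_a, start_b)
    if overlap <= 0:
        return 0.0, 0.0
    return overlap / (end_a - start_a), overlap / (end_b - start_b)


def intersect_callsets(A: Sequence[SVCall], B: Sequence[SVCall],
                       min_fraction: float = 0.9, reciprocal: bool = True,
                       same_type: bool = True) -> list:
    """Match records of A to records of B by (reciprocal) overlap fraction.

    A pair qualifies when the overlap covers >= min_fraction of A's record
    (and of B's when ``reciprocal``), and, when ``same_type``, the SV
    classes agree.  Each A record is matched to its single best-overlap B
    record (ties to the smaller B start).  Returns (a, b, frac_a, frac_b)
    tuples.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError(f"min_fraction {min_fraction} outside (0, 1]")
    trees = {}
    for b in B:
        key = (b.chrom, b.svtype if same_type else None)
        trees.setdefault(key, IntervalTree()).addi(b.start, b.end, b)
    matches = []
    for a in A:
        tree = trees.get((a.chrom, a.svtype if same_type else None))
        if tree is None:
            continue
        best = None
        for iv in tree.overlap(a.start, a.end):
            b = iv.data
            frac_a, frac_b = reciprocal_overlap(a, b)
            if frac_a < min_fraction or (reciprocal and frac_b < min_fraction):
                continue
            overlap_len = min(a.end, b.end) - max(a.start, b.start)
            cand = (-overlap_len, b.start, b, frac_a, frac_b)
            if best is None or cand[:2] < best[:2]:
                best = cand
        if best is not None:
            matches.append((a, best[2], best[3], best[4]))
    return matches


def matches_to_rows(matches) -> list:
    """(a_id, b_id, frac_a, frac_b) rows for TSV serialization."""
    return [(a.id, b.id, round(fa, 4), round(fb, 4)) for a, b, fa, fb in matches]
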