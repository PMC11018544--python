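"""Cascade accounting: stage size summaries, per-size-bin rejection tables
and the half-up percentage rounding convention used throughout.

Rejection percentages need an explicit denominator: heuristic filter rows
are conventionally fractions of the raw callset, while curator rows are
fractions of the genotype-frequency-filtered subset selected for review.
Mixing those conventions silently is the classic reporting trap, so the
denominator stage travels with every row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cascade import CascadeResult
from .intervals import SIZE_BIN_LABELS, size_bin
from .svio import SV_TYPES, SVCall


def percent_rejected(n_removed: int, n_denominator: int, decimals: int = 1) -> float:
    """100 * n_removed / n_denominator, rounded half-up to ``decimals``."""
    if n_denominator <= 0:
        raise ValueError("percentage undefined for a zero denominator")
    if not 0 <= n_removed <= n_denominator:
        raise ValueError(f"n_removed {n_removed} outside 0..{n_denominator}")
    q = Decimal(1).scaleb(-decimals)
    pct = (Decimal(n_removed) * 100 / Decimal(n_denominator)).quantize(q, rounding=ROUND_HALF_UP)
    return float(pct)


@dataclass
class StageSummary:
    """Per-class length summary of the calls retained at one stage."""

    stage: str
    svtype: str
    count: int
    max_len: Optional[int] = None
    min_len: Optional[int] = None
    mean_len: Optional[float] = None
    median_len: Optional[float] = None


def stage_summary(calls: Sequence[SVCall], stage: str = "") -> list:
    """Exact order statistics and mean of svlen per SV class.

    Classes absent from the input get a count-0 row with undefined lengths.
    """
    rows = []
    for svtype in SV_TYPES:
        lengths = np.array([c.svlen for c in calls if c.svtype == svtype])
        if lengths.size == 0:
            rows.append(StageSummary(stage=stage, svtype=svtype, count=0))
        else:
            rows.append(StageSummary(
                stage=stage, svtype=svtype, count=int(lengths.size),
                max_len=int(lengths.max()), min_len=int(lengths.min()),
                mean_len=float(lengths.mean()), median_len=float(np.median(lengths)),
            ))
    return rows


def stage_summary_frame(cascade: CascadeResult) -> pd.DataFrame:
    rows = stage_summary(cascade.input_calls, "raw")
    for rec in cascade.stages:
        rows += stage_summary(rec.retained, rec.name)
    return pd.DataFrame([vars(r) for r in rows])


@dataclass
class RejectionRow:
    """One (stage, class) row of per-size-bin rejection percentages."""

    stage: str
    svtype: str
    bin_pct: dict = field(default_factory=dict)
    total_pct: Optional[float] = None
    total_rejected: int = 0
    denominator_stage: str = ""


def _bin_counts(calls: Sequence[SVCall]) -> dict:
    counts = dict.fromkeys(SIZE_BIN_LABELS, 0)
    for c in calls:
        counts[size_bin(c.svlen)] += 1
    return counts


def rejection_table(cascade: CascadeResult, decimals: int = 1) -> list:
    """Per-size-bin percent-rejected rows for every (stage, SV class).

    Each stage's percentages are fractions of the population entering its
    declared denominator stage (``cascade.denominators``), restricted to
    the same size bin; bins with an empty denominator get no percentage.
    """
    rows = []
    for rec in cascade.stages:
        den_name = cascade.denominators.get(rec.name, rec.name)
        try:
            den_pop = cascade.stage(den_name).input
        except KeyError:
            raise ValueError(f"denominator stage {den_name!r} missing from ledger")
        for svtype in SV_TYPES:
            rejected = [c for c in rec.rejected if c.svtype == svtype]
            denom = [c for c in den_pop if c.svtype == svtype]
            rej_bins = _bin_counts(rejected)
            den_bins = _bin_counts(denom)
            row = RejectionRow(stage=rec.name, svtype=svtype,
                               total_rejected=len(rejected),
                               denominator_stage=den_name)
            for label in SIZE_BIN_LABELS:
                row.bin_pct[label] = (percent_rejected(rej_bins[label], den_bins[label], decimals)
                                      if den_bins[label] > 0 else None)
            if denom:
                row.total_pct = percent_rejected(len(rejected), len(denom), decimals)
            rows.append(row)
    return rows


def rejection_frame(rows: Sequence[RejectionRow]) -> pd.DataFrame:
    records = []
    for r in rows:
        rec = {"stage": r.stage, "svtype": r.svtype}
        rec.update(r.bin_pct)
        rec["total_pct"] = r.total_pct
        rec["total_rejected"] = r.total_rejected
        rec["denominator_stage"] = r.denominator_stage
        records.append(rec)
    return pd.DataFrame(records)
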